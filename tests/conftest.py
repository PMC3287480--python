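import numpy as np
import pytest

from fmb.core_selection import select_core
from fmb.flux_sampling import sample_flux_matrix
from fmb.model_io import MetabolicModel, Reaction
from fmb.synthetic import ToyModelSpec, make_toy_model


@pytest.fixture(scope="session")
def toy_fixture():
    return make_toy_model(ToyModelSpec())


@pytest.fixture(scope="session")
def toy_matrix(toy_fixture):
    """100 LAD-reconciled samples per condition on the toy network."""
    return sample_flux_matrix(toy_fixture.model, toy_fixture.constraints,
                              toy_fixture.perturbation, 100, master_seed=11)


@pytest.fixture(scope="session")
def toy_core(toy_matrix):
    return select_core(toy_matrix)


@pytest.fixture(scope="session")
def toy_files(toy_fixture, tmp_path_factory):
    return toy_fixture.emit(tmp_path_factory.mktemp("fixture"))


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """Random feasible toy LP instance: v = 0 always satisfies the bounds."""
    n_met = int(rng.integers(2, 5))
    n_rxn = int(rng.integers(3, 11))
    S = np.zeros((n_met, n_rxn))
    for j in range(n_rxn):
        rows = rng.choice(n_met, size=int(rng.integers(1, min(3, n_met) + 1)),
                          replace=False)
        for i in rows:
            c = 0
            while c == 0:
                c = int(rng.integers(-3, 4))
            S[i, j] = c
    reactions = []
    for j in range(n_rxn):
        lb = float(-rng.uniform(0.5, 10.0)) if rng.random() < 0.7 else 0.0
        ub = float(rng.uniform(0.5, 10.0))
        reactions.append(Reaction(f"R{j}", reversible=lb < 0,
                                  lower_bound=lb, upper_bound=ub))
    return MetabolicModel([f"m{i}" for i in range(n_met)], reactions, S)


def random_targets(model: MetabolicModel, rng: np.random.Generator) -> dict[str, float]:
    k = int(rng.integers(1, 4))
    ids = rng.choice(model.reaction_ids, size=min(k, len(model.reactions)),
                     replace=False)
    return {str(r): float(rng.uniform(-3, 3)) for r in ids}
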