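"""Synthetic fixtures: designed toy metabolic networks with known module
structure, and simulated discrete datasets for structure-learner checks.

The toy network routes a single substrate through ``n_modules`` parallel
linear chains that converge on a common product feeding biomass:

    EX_S (uptake, negative flux)
      -> two-step transport (Se0 -> Se1 -> S, one step runs in reverse so the
         transport pair shares the uptake's flux-variation pattern)
      -> module chains  S -> C -> C -> ... -> P   (one x2 amplification step
         per chain, so chain members are exactly proportional but not equal,
         plus one unit-coupled pair that IS an exact duplicate)
      -> biomass pair   P -> Pb -> (growth)

Measured constraints sit on the branch-split reactions (first reaction of
every chain except the last, isotope-traced class) and on the uptake exchange
(culture-rate class). The last chain is left unmeasured and absorbs the
balance, so every draw of randomized targets is exactly achievable: the LAD
residual is 0 and every flux is uniquely determined by the draws. The
perturbed condition knocks out the first chain's entry reaction and shifts
the measured means, rerouting flux through the sibling chains.

Ground truth: chain reactions are labelled by module; flux variation within a
module is perfectly correlated (correlation 1) and across modules it follows
independent draws, which is what the pattern-clustering stage must recover.
No true module is a singleton (singleton groups are not stably separable
under depth-2 inconsistency cutting), which is also why the transport and
biomass steps come in proportional pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayesnet import DiscretizedData
from .model_io import (
    ConstraintEntry,
    ExperimentalConstraints,
    MetabolicModel,
    PerturbationSpec,
    Reaction,
    write_constraints,
    write_model_tsv,
)
from .util import FMBError


@dataclass(frozen=True)
class ToyModelSpec:
    n_modules: int = 3
    reactions_per_module: int = 4
    sigma_scale: float = 0.05  # measurement sigma as a fraction of the mean
    knockout_module: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 2:
            raise FMBError("need at least 2 modules")
        if self.reactions_per_module < 2:
            raise FMBError("need at least 2 reactions per module")
        if not 1 <= self.knockout_module < self.n_modules:
            raise FMBError("knockout module must be a measured (non-absorber) chain")


@dataclass
class ToyFixture:
    model: MetabolicModel
    constraints: ExperimentalConstraints
    perturbation: PerturbationSpec
    module_of: dict[str, str]        # chain reaction id -> module label "M1".."Mn"
    responsive_ids: list[str]        # reactions expected to shift under perturbation
    spec: ToyModelSpec = field(default_factory=ToyModelSpec)

    def emit(self, out_dir: str | Path) -> dict[str, Path]:
        """Write model.tsv / constraints.csv / truth.json (ordinary I/O paths)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "model": out / "model.tsv",
            "constraints": out / "constraints.csv",
            "truth": out / "truth.json",
        }
        write_model_tsv(self.model, paths["model"])
        write_constraints(self.constraints, paths["constraints"])
        paths["truth"].write_text(json.dumps({
            "module_of": self.module_of,
            "responsive_ids": self.responsive_ids,
            "knockouts": list(self.perturbation.knockout_reaction_ids),
            "spec": {"n_modules": self.spec.n_modules,
                     "reactions_per_module": self.spec.reactions_per_module,
                     "sigma_scale": self.spec.sigma_scale,
                     "knockout_module": self.spec.knockout_module,
                     "seed": self.spec.seed},
        }, indent=2) + "\n")
        return paths


def _chain_ids(module: int, per_module: int) -> list[str]:
    return [f"M{module}R{j}" for j in range(1, per_module + 1)]


def make_toy_model(spec: ToyModelSpec = ToyModelSpec()) -> ToyFixture:
    """Build the toy model, its two-condition constraint table and ground truth."""
    n, per = spec.n_modules, spec.reactions_per_module
    reactions: list[Reaction] = []
    equations: dict[str, dict[str, float]] = {}

    def add(rid: str, coeffs: dict[str, float], reversible: bool = False,
            lb: float | None = None, ub: float = 1000.0, subsystem: str = "") -> None:
        if lb is None:
            lb = -1000.0 if reversible else 0.0
        reactions.append(Reaction(rid, subsystem=subsystem, reversible=reversible,
                                  lower_bound=lb, upper_bound=ub))
        equations[rid] = coeffs

    # transport: EX_S runs negative (uptake), TD runs negative too (same
    # variation pattern as EX_S); TP1/TP2 run positive, proportional to uptake
    add("EX_S", {"Se0": -1.0}, reversible=True, subsystem="Transport")
    add("TD", {"Se1": -1.0, "Se0": 2.0}, reversible=True, subsystem="Transport")
    add("TP1", {"Se1": -1.0, "Sp": 2.0}, subsystem="Transport")
    add("TP2", {"Sp": -1.0, "S": 1.0}, subsystem="Transport")

    module_of: dict[str, str] = {}
    for m in range(1, n + 1):
        ids = _chain_ids(m, per)
        mets = [f"C{m}_{j}" for j in range(1, per)]
        chain = ["S"] + mets + ["P"]
        for j, rid in enumerate(ids):
            # one x2 amplification at the second-to-last step keeps members
            # proportional-but-unequal; the first two reactions stay unit-coupled
            # (an exact duplicate pair exercising the collapse/reinsert path)
            prod_coef = 2.0 if j == per - 2 else 1.0
            add(rid, {chain[j]: -1.0, chain[j + 1]: prod_coef},
                subsystem=f"Module{m}")
            module_of[rid] = f"M{m}"

    add("BM1", {"P": -1.0, "Pb": 2.0}, subsystem="Biomass")
    add("BIOMASS", {"Pb": -1.0}, subsystem="Biomass")

    metabolites: list[str] = []
    seen: set[str] = set()
    for coeffs in equations.values():
        for met in coeffs:
            if met not in seen:
                seen.add(met)
                metabolites.append(met)
    S = np.zeros((len(metabolites), len(reactions)))
    met_index = {m: i for i, m in enumerate(metabolites)}
    for j, r in enumerate(reactions):
        for met, c in equations[r.id].items():
            S[met_index[met], j] = c
    model = MetabolicModel(metabolites, reactions, S, biomass_reaction_id="BIOMASS")

    # measured means: chains 1..n-1 measured, chain n absorbs the balance
    control_means = {f"M{m}R1": 1.0 + 0.5 * (m - 1) for m in range(1, n)}
    uptake_c = sum(control_means.values()) + (1.0 + 0.5 * (n - 1))  # absorber mean
    perturbed_means = {}
    for m in range(1, n):
        if m == spec.knockout_module:
            perturbed_means[f"M{m}R1"] = 0.0
        else:
            perturbed_means[f"M{m}R1"] = control_means[f"M{m}R1"] * 1.3
    uptake_p = uptake_c * 0.93
    absorber_p = uptake_p - sum(perturbed_means.values())
    if absorber_p <= 3 * spec.sigma_scale * uptake_p:
        raise FMBError("designed means leave no slack for the absorber chain")

    entries: list[ConstraintEntry] = []
    for cond, means, uptake in (("control", control_means, uptake_c),
                                ("perturbed", perturbed_means, uptake_p)):
        for rid, mu in means.items():
            entries.append(ConstraintEntry(rid, cond, mu, spec.sigma_scale * mu, "C13"))
        entries.append(ConstraintEntry("EX_S", cond, -uptake,
                                       0.4 * spec.sigma_scale * uptake, "FMT"))
    constraints = ExperimentalConstraints(entries)
    constraints.validate_against(model)

    knock_id = f"M{spec.knockout_module}R1"
    perturbation = PerturbationSpec.from_ids([knock_id], label=f"{knock_id}-knockout")
    # every flux is proportional to a measured quantity that shifts between
    # conditions, so all internal and transport reactions are responsive
    responsive = sorted(module_of) + ["EX_S", "TD", "TP1", "TP2", "BM1", "BIOMASS"]
    return ToyFixture(model, constraints, perturbation, module_of, responsive, spec)


def two_branch_model() -> MetabolicModel:
    """Minimal redundancy fixture: uptake capped at 1, two parallel branches
    capped at 0.5 each, one dead-end side reaction; max growth is 1.0, either
    branch deletion halves it."""
    reactions = [
        Reaction("EX_S", lower_bound=-1.0, upper_bound=0.0, reversible=True),
        Reaction("T1", lower_bound=0.0, upper_bound=1000.0, reversible=False),
        Reaction("BR_A", lower_bound=0.0, upper_bound=0.5, reversible=False),
        Reaction("BR_B", lower_bound=0.0, upper_bound=0.5, reversible=False),
        Reaction("SIDE", lower_bound=0.0, upper_bound=1000.0, reversible=False),
        Reaction("EX_W", lower_bound=0.0, upper_bound=1000.0, reversible=False),
        Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0, reversible=False),
    ]
    metabolites = ["Se", "S", "P", "W"]
    S = np.zeros((4, 7))
    cols = {
        "EX_S": {"Se": -1.0},
        "T1": {"Se": -1.0, "S": 1.0},
        "BR_A": {"S": -1.0, "P": 1.0},
        "BR_B": {"S": -1.0, "P": 1.0},
        "SIDE": {"S": -1.0, "W": 1.0},
        "EX_W": {"W": -1.0},
        "BIOMASS": {"P": -1.0},
    }
    met_index = {m: i for i, m in enumerate(metabolites)}
    for j, r in enumerate(reactions):
        for met, c in cols[r.id].items():
            S[met_index[met], j] = c
    return MetabolicModel(metabolites, reactions, S, biomass_reaction_id="BIOMASS")


# ---------------------------------------------------------------------------
# Simulated discrete datasets for the structure learner
# ---------------------------------------------------------------------------

def simulate_bn_dataset(parents: dict[str, tuple[str, ...]],
                        cpts: dict[str, np.ndarray],
                        n_samples: int, seed: int = 0) -> DiscretizedData:
    """Ancestral sampling from a discrete network.

    ``cpts[node]`` has shape (q, r): one row per parent configuration (mixed
    radix over the node's parent tuple order, most significant first), each
    row a distribution over the node's r states.
    """
    from .bayesnet import _check_acyclic

    _check_acyclic(parents)
    nodes = sorted(parents)
    cards = {n: cpts[n].shape[1] for n in nodes}
    for node, table in cpts.items():
        if not np.allclose(table.sum(axis=1), 1.0):
            raise ValueError(f"CPT rows for {node!r} must sum to 1")
    # topological order
    order: list[str] = []
    placed: set[str] = set()
    while len(order) < len(nodes):
        for node in nodes:
            if node not in placed and all(p in placed for p in parents[node]):
                order.append(node)
                placed.add(node)
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    for node in order:
        ps = parents[node]
        config = np.zeros(n_samples, dtype=np.int64)
        for p in ps:
            config = config * cards[p] + samples[p]
        table = cpts[node]
        u = rng.random(n_samples)
        cdf = np.cumsum(table, axis=1)
        samples[node] = (u[:, None] > cdf[config]).sum(axis=1)
    bins = np.stack([samples[n] for n in nodes])
    return DiscretizedData(nodes, bins, [cards[n] for n in nodes])
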