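"""Flux-matrix generation: LAD-reconciled flux analysis under randomized constraints.

Each sample draws one randomized target per measured reaction (a normal draw
truncated to one standard deviation around the reported mean, so random errors
stay within the measurement's standard error), then solves a least-absolute-
deviation (LAD) linear program that reconciles the steady-state flux vector
with those targets:

    minimize   sum_k |v_k - target_k|
    subject to S v = 0,  alpha <= v <= beta

solved as an LP with positive/negative deviation variables. The LAD optimum is
generally degenerate in the unmeasured fluxes, so a secondary LP holds the
measured fluxes at their achieved values and minimizes sum_j |v_j|
(parsimonious flux distribution); sampling variability then comes only from
the randomized targets. Iterating per condition and merging the columns gives
the reactions-by-samples *flux matrix* that all downstream stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import ExperimentalConstraints, MetabolicModel, PerturbationSpec, apply_knockout
from .util import InfeasibleProblemError, column_rng

CONDITION_INDEX = {"control": 0, "perturbed": 1}


@dataclass
class FluxMatrix:
    """N reactions x M samples of reconciled fluxes, both conditions merged."""

    values: np.ndarray
    reaction_ids: list[str]
    conditions: list[str]  # per-column condition label
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.reaction_ids), len(self.conditions)):
            raise ValueError("flux matrix shape inconsistent with row/column labels")

    @property
    def n_reactions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([c == condition for c in self.conditions])

    def restrict(self, reaction_ids: Sequence[str]) -> "FluxMatrix":
        index = {rid: i for i, rid in enumerate(self.reaction_ids)}
        rows = [index[r] for r in reaction_ids]
        return FluxMatrix(self.values[rows], list(reaction_ids), list(self.conditions),
                          dict(self.provenance))

    # -- persistence (TSV, header "condition:index") -------------------
    def to_tsv(self, path: str | Path) -> None:
        counters: dict[str, int] = {}
        cols = []
        for c in self.conditions:
            counters[c] = counters.get(c, 0) + 1
            cols.append(f"{c}:{counters[c] - 1}")
        df = pd.DataFrame(self.values, index=self.reaction_ids, columns=cols)
        df.to_csv(path, sep="\t", index_label="reaction_id", float_format="%.12g")

    @staticmethod
    def from_tsv(path: str | Path) -> "FluxMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        conditions = [c.rsplit(":", 1)[0] for c in df.columns]
        return FluxMatrix(df.to_numpy(float), [str(i) for i in df.index], conditions)


@dataclass
class RandomizedTargets:
    """One randomized target flux per measured reaction, |target - mu| <= sigma."""

    targets: dict[str, float]
    means: dict[str, float]
    sigmas: dict[str, float]

    def __post_init__(self) -> None:
        for rid, t in self.targets.items():
            if abs(t - self.means[rid]) > self.sigmas[rid] + 1e-12:
                raise ValueError(f"target for {rid} outside mu +/- sigma")


def draw_constraint_targets(
    constraints: ExperimentalConstraints,
    condition: str,
    rng: np.random.Generator | int,
) -> RandomizedTargets:
    """Draw randomized targets: normal(mu, sigma) truncated to [mu-sigma, mu+sigma].

    Rejection sampling keeps the truncated-normal shape (no probability mass
    piles up at the endpoints); sigma = 0 degenerates to the mean exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    targets: dict[str, float] = {}
    means: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    for entry in constraints.for_condition(condition):
        if entry.sigma == 0.0:
            draw = entry.mean
        else:
            while True:
                draw = rng.normal(entry.mean, entry.sigma)
                if abs(draw - entry.mean) <= entry.sigma:
                    break
        targets[entry.reaction_id] = draw
        means[entry.reaction_id] = entry.mean
        sigmas[entry.reaction_id] = entry.sigma
    return RandomizedTargets(targets, means, sigmas)


# ---------------------------------------------------------------------------
# LAD LP
# ---------------------------------------------------------------------------

def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    return res


def solve_lad_fba(
    model: MetabolicModel,
    targets: RandomizedTargets | Mapping[str, float],
) -> tuple[np.ndarray, float]:
    """Reconcile a steady-state flux vector with measured targets in L1.

    Returns ``(v, residual)`` where ``residual`` is the minimal achievable
    L1 deviation. Raises :class:`InfeasibleProblemError` when no steady-state
    flux vector satisfies the bounds at all.
    """
    target_map = targets.targets if isinstance(targets, RandomizedTargets) else dict(targets)
    index = model.reaction_index
    missing = [r for r in target_map if r not in index]
    if missing:
        raise InfeasibleProblemError(f"targets reference unknown reactions: {missing}")
    n = len(model.reactions)
    k_ids = sorted(target_map)
    k_idx = [index[r] for r in k_ids]
    m = len(k_ids)

    # variables: [v (n), d_plus (m), d_minus (m)]
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    A_eq = np.zeros((model.S.shape[0] + m, n + 2 * m))
    A_eq[: model.S.shape[0], :n] = model.S
    b_eq = np.zeros(model.S.shape[0] + m)
    for row, (j, rid) in enumerate(zip(k_idx, k_ids), start=model.S.shape[0]):
        A_eq[row, j] = 1.0
        A_eq[row, n + (row - model.S.shape[0])] = -1.0
        A_eq[row, n + m + (row - model.S.shape[0])] = 1.0
        b_eq[row] = target_map[rid]
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions] + [(0, None)] * (2 * m)
    res = _solve(c, None, None, A_eq, b_eq, bounds)
    if res.status != 0:
        raise InfeasibleProblemError(
            f"LAD reconciliation infeasible (status {res.status}): {res.message}; "
            f"constrained reactions: {k_ids}"
        )
    residual = float(res.fun)
    achieved = {rid: float(res.x[j]) for rid, j in zip(k_ids, k_idx)}

    # Secondary parsimony LP: fix measured fluxes at achieved values, minimize
    # sum |v| to resolve degeneracy among the unmeasured fluxes.
    # variables: [v (n), t (n)], t_j >= |v_j|
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq2 = np.zeros((model.S.shape[0], 2 * n))
    A_eq2[:, :n] = model.S
    b_eq2 = np.zeros(model.S.shape[0])
    eye = np.eye(n)
    A_ub2 = np.block([[eye, -eye], [-eye, -eye]])
    b_ub2 = np.zeros(2 * n)
    bounds2 = []
    for j, r in enumerate(model.reactions):
        bounds2.append((r.lower_bound, r.upper_bound))
    for rid, j in zip(k_ids, k_idx):
        lo, hi = bounds2[j]
        val = min(max(achieved[rid], lo), hi)
        bounds2[j] = (val, val)
    bounds2 += [(0, None)] * n
    res2 = _solve(c2, A_ub2, b_ub2, A_eq2, b_eq2, bounds2)
    if res2.status != 0:  # pragma: no cover - primary solution is feasible here
        raise InfeasibleProblemError(f"parsimony LP failed (status {res2.status}): {res2.message}")
    v = np.asarray(res2.x[:n], dtype=float)
    return v, residual


def sample_flux_matrix(
    model: MetabolicModel,
    constraints: ExperimentalConstraints,
    perturbation: PerturbationSpec,
    n_per_condition: int,
    master_seed: int,
) -> FluxMatrix:
    """Generate the merged flux matrix: ``n_per_condition`` columns per condition.

    Control columns use the unmodified model; perturbed columns the knockout
    model. Per-column generators are derived deterministically from
    ``master_seed`` and (condition, sample index), so either condition can be
    regenerated independently.
    """
    if n_per_condition < 2:
        raise ValueError("n_per_condition must be >= 2")
    constraints.validate_against(model)
    models = {"control": model, "perturbed": apply_knockout(model, perturbation)}
    values = np.empty((len(model.reactions), 2 * n_per_condition))
    conditions: list[str] = []
    residuals = np.empty(2 * n_per_condition)
    col = 0
    for condition in ("control", "perturbed"):
        cond_model = models[condition]
        for i in range(n_per_condition):
            rng = column_rng(master_seed, CONDITION_INDEX[condition], i)
            targets = draw_constraint_targets(constraints, condition, rng)
            try:
                v, resid = solve_lad_fba(cond_model, targets)
            except InfeasibleProblemError as exc:
                raise InfeasibleProblemError(
                    f"sample {i} of condition {condition!r}: {exc}"
                ) from exc
            values[:, col] = v
            residuals[col] = resid
            conditions.append(condition)
            col += 1
    return FluxMatrix(
        values, model.reaction_ids, conditions,
        provenance={
            "master_seed": int(master_seed),
            "n_per_condition": int(n_per_condition),
            "knockouts": list(perturbation.knockout_reaction_ids),
            "residuals": residuals.tolist(),
        },
    )
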