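"""Core-reaction selection: the filter cascade reducing the flux matrix.

Three filters, applied in order:

1. **Significance** — a paired t-test per reaction comparing the control and
   perturbed flux samples (paired by sample index); reactions with two-sided
   P below the threshold (default 1e-2, no multiplicity correction) are kept
   as significantly perturbation-responsive.
2. **Activity** — keep reactions carrying non-zero flux (|v| > 1e-6) in
   strictly more than 95% of samples of at least one condition.
3. **Duplicate collapse** — reactions with identical rows across all samples
   (stoichiometrically coupled sets) are represented by their
   lexicographically smallest member; removed members are remembered so they
   can be reinserted into their representative's cluster later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .flux_sampling import FluxMatrix
from .util import DUPLICATE_TOL, FMBError, ZERO_TOL


class EmptyCoreError(FMBError):
    """No reaction survived the core-selection cascade."""


def paired_t_test(matrix: FluxMatrix, control: str = "control",
                  perturbed: str = "perturbed") -> np.ndarray:
    """Two-sided paired-t p-value per reaction, pairing samples by index.

    Zero-variance differences get p = 1 when the mean difference is zero
    (no evidence of change) and p = 0 otherwise (a deterministic shift).
    """
    a = matrix.values[:, matrix.condition_mask(control)]
    b = matrix.values[:, matrix.condition_mask(perturbed)]
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"unequal sample counts: {a.shape[1]} {control} vs {b.shape[1]} {perturbed}"
        )
    if a.shape[1] < 2:
        raise ValueError("paired t-test needs at least 2 sample pairs")
    d = a - b
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.empty(matrix.n_reactions)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p[~degenerate] = 2.0 * stats.t.sf(np.abs(t[~degenerate]), df=n - 1)
    p[degenerate] = np.where(mean[degenerate] == 0.0, 1.0, 0.0)
    return p


def activity_fraction(matrix: FluxMatrix, condition: str, tol: float = ZERO_TOL) -> np.ndarray:
    """Fraction of the condition's samples in which each reaction carries flux."""
    cols = matrix.values[:, matrix.condition_mask(condition)]
    if cols.shape[1] == 0:
        raise ValueError(f"condition {condition!r} has no columns")
    return (np.abs(cols) > tol).mean(axis=1)


def find_duplicates(values: np.ndarray, ids: list[str],
                    tol: float = DUPLICATE_TOL) -> dict[str, list[str]]:
    """Group reactions whose rows agree within *tol* in max-norm.

    Returns ``{representative_id: [other members...]}`` for groups of size >= 2;
    the representative is the lexicographically smallest id. The relation is
    closed transitively (union-find), so chained near-matches share a group.
    """
    n = len(ids)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    values = np.asarray(values, dtype=float)
    for i in range(n - 1):
        # one vectorized sweep per row; union-find closes chains transitively
        close = np.flatnonzero(np.max(np.abs(values[i + 1:] - values[i]), axis=1) <= tol)
        for j in close:
            ri, rj = find(i), find(int(j) + i + 1)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out: dict[str, list[str]] = {}
    for members in groups.values():
        if len(members) < 2:
            continue
        names = sorted(ids[i] for i in members)
        out[names[0]] = names[1:]
    return out


@dataclass
class CoreSelectionResult:
    p_values: dict[str, float]
    activity: dict[str, dict[str, float]]  # condition -> reaction -> fraction
    significant_ids: list[str]
    active_ids: list[str]
    duplicate_groups: dict[str, list[str]] = field(default_factory=dict)
    core_reaction_ids: list[str] = field(default_factory=list)
    reduced_matrix: FluxMatrix | None = None

    @property
    def counts(self) -> dict[str, int]:
        return {
            "initial": len(self.p_values),
            "significant": len(self.significant_ids),
            "active": len(self.active_ids),
            "core": len(self.core_reaction_ids),
        }


def select_core(matrix: FluxMatrix, p_thresh: float = 1e-2,
                act_thresh: float = 0.95, zero_tol: float = ZERO_TOL,
                duplicate_tol: float = DUPLICATE_TOL) -> CoreSelectionResult:
    """Run the full cascade: significance -> activity -> duplicate collapse.

    The activity rule is a strict ">" comparison ("more than 95% of samples"
    in either condition). Raises :class:`EmptyCoreError` if nothing survives.
    """
    ids = matrix.reaction_ids
    p = paired_t_test(matrix)
    act = {cond: activity_fraction(matrix, cond, zero_tol)
           for cond in ("control", "perturbed")}

    sig_mask = p < p_thresh
    act_mask = (act["control"] > act_thresh) | (act["perturbed"] > act_thresh)
    keep_mask = sig_mask & act_mask
    significant_ids = [ids[i] for i in np.flatnonzero(sig_mask)]
    active_ids = [ids[i] for i in np.flatnonzero(keep_mask)]
    if not active_ids:
        raise EmptyCoreError(
            f"no core reactions at P<{p_thresh} and activity>{act_thresh}"
        )
    kept_rows = np.flatnonzero(keep_mask)
    groups = find_duplicates(matrix.values[kept_rows], active_ids, duplicate_tol)
    removed = {m for members in groups.values() for m in members}
    core_ids = [rid for rid in active_ids if rid not in removed]
    return CoreSelectionResult(
        p_values=dict(zip(ids, p.tolist())),
        activity={c: dict(zip(ids, a.tolist())) for c, a in act.items()},
        significant_ids=significant_ids,
        active_ids=active_ids,
        duplicate_groups=groups,
        core_reaction_ids=core_ids,
        reduced_matrix=matrix.restrict(core_ids),
    )
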