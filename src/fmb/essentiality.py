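"""Reaction essentiality by single-deletion flux balance analysis.

For each reaction, growth (biomass flux) is maximized with that reaction's
bounds pinned to zero, and the essentiality is

    e = clamp(1 - g_deletion / g_reference, 0, 1)

so e = 0 means the deletion leaves growth unchanged (or improves it) and
e = 1 means growth stops entirely (an infeasible deletion LP also scores 1).

Experimental constraints enter these FBA problems as mean +/- sigma intervals
intersected with the model bounds, except the growth-rate measurement itself,
which is removed: with growth pinned to its measured value, maximizing growth
would be vacuous and every deletion would be either neutral or infeasible.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import ExperimentalConstraints, MetabolicModel
from .modularization import ClusterAssignment
from .util import InfeasibleProblemError


def constrained_model(model: MetabolicModel, constraints: ExperimentalConstraints | None,
                      condition: str | None) -> MetabolicModel:
    """Intersect bounds with measured mu +/- sigma intervals (growth excluded)."""
    out = model.copy()
    if constraints is None or condition is None:
        return out
    index = out.reaction_index
    for entry in constraints.for_condition(condition):
        if entry.reaction_id == model.biomass_reaction_id:
            continue  # the growth measurement is dropped for growth maximization
        j = index[entry.reaction_id]
        r = out.reactions[j]
        lo = max(r.lower_bound, entry.mean - entry.sigma)
        hi = min(r.upper_bound, entry.mean + entry.sigma)
        if lo > hi:
            raise InfeasibleProblemError(
                f"constraint interval for {entry.reaction_id} ({lo}, {hi}) "
                "does not intersect the model bounds"
            )
        out.reactions[j] = replace(r, lower_bound=lo, upper_bound=hi)
    return out


def max_growth(model: MetabolicModel, constraints: ExperimentalConstraints | None = None,
               condition: str | None = None) -> float:
    """LP maximum of biomass flux under steady state, bounds and constraint intervals."""
    if model.biomass_reaction_id is None:
        raise InfeasibleProblemError("model has no biomass reaction designated")
    work = constrained_model(model, constraints, condition)
    n = len(work.reactions)
    c = np.zeros(n)
    c[work.reaction_index[work.biomass_reaction_id]] = -1.0
    res = linprog(c, A_eq=work.S, b_eq=np.zeros(work.S.shape[0]),
                  bounds=list(zip(work.lower_bounds, work.upper_bounds)),
                  method="highs")
    if res.status != 0:
        raise InfeasibleProblemError(
            f"growth maximization infeasible (status {res.status}): {res.message}"
        )
    return float(-res.fun)


def reaction_essentiality(model: MetabolicModel, constraints: ExperimentalConstraints | None,
                          reaction_id: str, condition: str | None = None,
                          g_ref: float | None = None) -> float:
    """Essentiality of deleting one reaction; requires positive reference growth."""
    if reaction_id not in model.reaction_index:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    if g_ref is None:
        g_ref = max_growth(model, constraints, condition)
    if g_ref <= 0:
        raise InfeasibleProblemError("reference growth rate is zero; essentiality undefined")
    g_del = deletion_growth(model, constraints, reaction_id, condition)
    return float(min(max(1.0 - g_del / g_ref, 0.0), 1.0))


def deletion_growth(model: MetabolicModel, constraints: ExperimentalConstraints | None,
                    reaction_id: str, condition: str | None = None) -> float:
    """Max growth with one reaction's bounds pinned to zero (0 if infeasible)."""
    deleted = model.copy()
    j = deleted.reaction_index[reaction_id]
    deleted.reactions[j] = replace(deleted.reactions[j], lower_bound=0.0, upper_bound=0.0)
    try:
        return max_growth(deleted, constraints, condition)
    except InfeasibleProblemError:
        return 0.0


def essentiality_table(model: MetabolicModel,
                       constraints: ExperimentalConstraints | None = None,
                       conditions: tuple[str, ...] = ("control", "perturbed"),
                       assignment: ClusterAssignment | None = None) -> pd.DataFrame:
    """Per-reaction, per-condition essentiality with optional cluster ids.

    Columns: reaction_id, condition, g_ref, g_del, essentiality, cluster_id
    (cluster_id is NA for unclustered reactions or when no assignment given).
    """
    rows = []
    labels = assignment.labels if assignment is not None else {}
    for condition in conditions:
        cond = condition if constraints is not None else None
        g_ref = max_growth(model, constraints, cond)
        for r in model.reactions:
            g_del = deletion_growth(model, constraints, r.id, cond)
            e = float(min(max(1.0 - g_del / g_ref, 0.0), 1.0))
            rows.append({
                "reaction_id": r.id, "condition": condition,
                "g_ref": g_ref, "g_del": g_del,
                "essentiality": e,
                "cluster_id": labels.get(r.id, pd.NA),
            })
    return pd.DataFrame(rows)


def essentiality_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean essentiality per condition, overall and over clustered reactions,
    plus per-cluster unweighted means."""
    rows = []
    for condition, sub in table.groupby("condition"):
        rows.append({"condition": condition, "scope": "all", "cluster_id": pd.NA,
                     "mean_essentiality": sub["essentiality"].mean()})
        clustered = sub[sub["cluster_id"].notna()]
        if len(clustered):
            rows.append({"condition": condition, "scope": "clustered", "cluster_id": pd.NA,
                         "mean_essentiality": clustered["essentiality"].mean()})
            for cid, csub in clustered.groupby("cluster_id"):
                rows.append({"condition": condition, "scope": "cluster", "cluster_id": cid,
                             "mean_essentiality": csub["essentiality"].mean()})
    return pd.DataFrame(rows)
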