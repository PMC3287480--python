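"""Modularization: flux-pattern encoding and hierarchical clustering of reactions.

The reduced flux matrix is converted to {-1, 0, 1} *flux-pattern* matrices:
entry (n, m) is the sign of the flux change of reaction n between consecutive
(permuted) samples m and m+1, with changes below the zero tolerance encoded as
0. Many pattern matrices from independent random column permutations are
adjoined horizontally, and reactions are clustered on Euclidean distances
between their adjoined pattern rows with average linkage. Flat modules are cut
where the dendrogram's inconsistency coefficient (depth 2) exceeds the cutoff,
mirroring Matlab's ``clusterdata`` semantics at cutoff <= 2; a raw-distance
criterion is available for sensitivity analysis. Reactions removed as
duplicates rejoin their representative's module afterwards.

Pairwise distances are accumulated permutation block by block (squared
Euclidean distances add across concatenated blocks), so the full adjoined
matrix never needs to be materialized; results are identical to the naive
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, inconsistent, linkage
from scipy.spatial.distance import pdist

from .util import ZERO_TOL


def to_flux_pattern(values: np.ndarray, permutation: Sequence[int] | None = None,
                    tol: float = ZERO_TOL) -> np.ndarray:
    """Sign-of-change encoding of one column ordering.

    ``P[n, m] = sign(v[n, perm[m+1]] - v[n, perm[m]])`` with differences of
    magnitude <= *tol* encoded as 0. Output dtype is int8, width M-1.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    if permutation is None:
        permutation = np.arange(m)
    permutation = np.asarray(permutation)
    if sorted(permutation.tolist()) != list(range(m)):
        raise ValueError("permutation must be a bijection on the column indices")
    ordered = values[:, permutation]
    diff = ordered[:, 1:] - ordered[:, :-1]
    pattern = np.zeros_like(diff, dtype=np.int8)
    pattern[diff > tol] = 1
    pattern[diff < -tol] = -1
    return pattern


def _permutations(m: int, n_perms: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [rng.permutation(m) for _ in range(n_perms)]


def build_adjoined_pattern(values: np.ndarray, n_perms: int = 300, seed: int = 0,
                           tol: float = ZERO_TOL,
                           permutations: Sequence[Sequence[int]] | None = None) -> np.ndarray:
    """Adjoin pattern matrices from *n_perms* independent random permutations.

    Shape: N x n_perms*(M-1). Mostly useful for small inputs and oracles;
    :func:`pattern_distances` computes the same geometry blockwise.
    """
    if permutations is None:
        if n_perms < 1:
            raise ValueError("n_perms must be >= 1")
        permutations = _permutations(values.shape[1], n_perms, seed)
    blocks = [to_flux_pattern(values, p, tol) for p in permutations]
    return np.concatenate(blocks, axis=1)


def pattern_distances(values: np.ndarray, n_perms: int = 300, seed: int = 0,
                      tol: float = ZERO_TOL,
                      permutations: Sequence[Sequence[int]] | None = None) -> np.ndarray:
    """Condensed Euclidean distances between adjoined pattern rows, blockwise."""
    if permutations is None:
        permutations = _permutations(values.shape[1], n_perms, seed)
    n = values.shape[0]
    sq = np.zeros(n * (n - 1) // 2)
    for p in permutations:
        block = to_flux_pattern(values, p, tol).astype(float)
        sq += pdist(block, metric="sqeuclidean")
    return np.sqrt(sq)


@dataclass
class ClusterAssignment:
    """Reaction -> module map plus the dendrogram it came from."""

    labels: dict[str, int]
    linkage_matrix: np.ndarray | None = None
    inconsistency: np.ndarray | None = None
    duplicates_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(r for r, c in self.labels.items() if c == cluster_id)

    def clusters(self) -> dict[int, list[str]]:
        return {c: self.members(c) for c in sorted(set(self.labels.values()))}


def _renumber(raw: np.ndarray, ids: Sequence[str]) -> dict[str, int]:
    """Deterministic cluster ids: 1..C ascending by smallest member row index."""
    order: dict[int, int] = {}
    for i, lab in enumerate(raw):
        order.setdefault(int(lab), i)
    ranked = sorted(order, key=order.get)
    remap = {lab: rank + 1 for rank, lab in enumerate(ranked)}
    return {ids[i]: remap[int(raw[i])] for i in range(len(ids))}


def hierarchical_cluster(pattern_or_distances: np.ndarray, ids: Sequence[str],
                         cutoff: float = 1.0, criterion: str = "inconsistent",
                         depth: int = 2, condensed: bool = False) -> ClusterAssignment:
    """Average-linkage clustering of pattern rows with dendrogram cutting.

    *criterion* is ``"inconsistent"`` (default, depth-2 inconsistency
    coefficient compared against *cutoff*) or ``"distance"`` (raw cophenetic
    height). A single row yields one singleton cluster.
    """
    ids = list(ids)
    if condensed:
        dists = np.asarray(pattern_or_distances, dtype=float)
    else:
        mat = np.asarray(pattern_or_distances, dtype=float)
        if mat.shape[0] != len(ids):
            raise ValueError("row count does not match ids")
        if mat.shape[0] == 1:
            return ClusterAssignment({ids[0]: 1})
        dists = pdist(mat, metric="euclidean")
    if len(ids) == 1:
        return ClusterAssignment({ids[0]: 1})
    Z = linkage(dists, method="average")
    R = inconsistent(Z, d=depth)
    if criterion == "inconsistent":
        raw = fcluster(Z, t=cutoff, criterion="inconsistent", R=R)
    elif criterion == "distance":
        raw = fcluster(Z, t=cutoff, criterion="distance")
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return ClusterAssignment(_renumber(raw, ids), Z, R)


def cluster_core_reactions(reduced_values: np.ndarray, ids: Sequence[str],
                           n_perms: int = 300, cutoff: float = 1.0, seed: int = 0,
                           criterion: str = "inconsistent",
                           tol: float = ZERO_TOL) -> ClusterAssignment:
    """Full modularization of the reduced flux matrix (blockwise distances)."""
    ids = list(ids)
    if len(ids) == 1:
        return ClusterAssignment({ids[0]: 1})
    dists = pattern_distances(reduced_values, n_perms=n_perms, seed=seed, tol=tol)
    return hierarchical_cluster(dists, ids, cutoff=cutoff, criterion=criterion,
                                condensed=True)


def reinsert_duplicates(assignment: ClusterAssignment,
                        duplicate_groups: dict[str, list[str]]) -> ClusterAssignment:
    """Place each collapsed duplicate into its representative's module."""
    labels = dict(assignment.labels)
    duplicates_of = dict(assignment.duplicates_of)
    for rep, members in duplicate_groups.items():
        if rep not in labels:
            raise KeyError(f"duplicate-group representative {rep!r} is not clustered")
        for member in members:
            labels[member] = labels[rep]
            duplicates_of[member] = rep
    return ClusterAssignment(labels, assignment.linkage_matrix,
                             assignment.inconsistency, duplicates_of)
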