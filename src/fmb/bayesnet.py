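"""Discrete Bayesian networks over reaction fluxes: discretization, MI/TMI,
MDL-scored tabu structure search, and local/global network learning.

Continuous fluxes are discretized by the equal-frequency method into four
intervals (computed once over the full merged sample set, so local networks,
the global network, and all MI/TMI values share one discretization). Structure
learning is score-based local search over DAG space with add/delete/reverse
arc moves, a tabu list of recently applied moves, acceptance of the best
non-tabu neighbour even when it worsens the score (tabu escape), best-ever
tracking and random restarts. The score is minimum description length in bits,

    MDL(G) = log2(M)/2 * sum_i q_i (r_i - 1)  +  sum_i M * H(X_i | Pa_i),

with ``r_i`` the state count of node i, ``q_i`` the number of parent
configurations, and the conditional entropies taken at the maximum-likelihood
(unsmoothed) frequencies; lower is better. Reported conditional probability
tables use Laplace (+1) smoothing.

Module influence is summarized by total mutual information: TMI of a reaction
is the sum of its pairwise empirical mutual informations (in bits) against the
other members of its module; the member with maximal TMI is the module's
representative in the global network.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .util import FMBError


# ---------------------------------------------------------------------------
# Equal-frequency discretization
# ---------------------------------------------------------------------------

def discretize_equal_frequency(values: Sequence[float], k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Bin one variable into *k* equal-frequency intervals.

    Edges sit at the k-quantiles of the empirical distribution; a value equal
    to an edge falls in the lower bin, so equal values always share a bin.
    With fewer distinct values than *k* the binning collapses (with a warning)
    to the number of distinct values actually separable.

    Returns ``(bin_indices, edges)`` with bins relabelled to consecutive
    integers 0..r-1 over the occupied bins.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D sample vector")
    if values.size < k:
        raise ValueError(f"need at least k={k} samples, got {values.size}")
    edges = np.unique(np.quantile(values, [j / k for j in range(1, k)]))
    bins = np.searchsorted(edges, values, side="left")
    occupied = np.unique(bins)
    if occupied.size < k:
        warnings.warn(
            f"equal-frequency binning collapsed to {occupied.size} bins (< {k})",
            stacklevel=2,
        )
    remap = {int(b): i for i, b in enumerate(occupied)}
    bins = np.array([remap[int(b)] for b in bins], dtype=np.int64)
    return bins, edges


@dataclass
class DiscretizedData:
    """Per-variable bin indices for a set of variables over shared samples."""

    ids: list[str]
    bins: np.ndarray          # variables x samples, int
    cardinalities: list[int]  # states per variable
    edges: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        if self.bins.shape[0] != len(self.ids):
            raise ValueError("bins row count != number of ids")

    @property
    def n_samples(self) -> int:
        return self.bins.shape[1]

    def index(self, rid: str) -> int:
        return self.ids.index(rid)

    def restrict(self, ids: Sequence[str]) -> "DiscretizedData":
        rows = [self.index(r) for r in ids]
        return DiscretizedData(list(ids), self.bins[rows],
                               [self.cardinalities[r] for r in rows],
                               [self.edges[r] for r in rows] if self.edges else [])

    @classmethod
    def from_values(cls, values: np.ndarray, ids: Sequence[str], k: int = 4) -> "DiscretizedData":
        """Discretize each row of a flux matrix jointly over all its columns."""
        values = np.asarray(values, dtype=float)
        bins = np.empty(values.shape, dtype=np.int64)
        cards, edges = [], []
        for i in range(values.shape[0]):
            b, e = discretize_equal_frequency(values[i], k)
            bins[i] = b
            cards.append(int(b.max()) + 1)
            edges.append(e)
        return cls(list(ids), bins, cards, edges)


# ---------------------------------------------------------------------------
# Mutual information / TMI
# ---------------------------------------------------------------------------

def empirical_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Empirical mutual information in bits; 0*log(0) terms contribute 0."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    rx, ry = int(x.max()) + 1, int(y.max()) + 1
    joint = np.bincount(x * ry + y, minlength=rx * ry).reshape(rx, ry) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))


def tmi(data: DiscretizedData, target: str, members: Iterable[str]) -> float:
    """Total mutual information: sum of pairwise MI of *target* vs the rest."""
    t = data.bins[data.index(target)]
    total = 0.0
    for rid in members:
        if rid == target:
            continue
        total += empirical_mi(t, data.bins[data.index(rid)])
    return total


def select_representative(members: Sequence[str], data: DiscretizedData) -> tuple[str, dict[str, float]]:
    """The member with maximal TMI; ties broken by lexicographic id order."""
    members = sorted(members)
    if not members:
        raise ValueError("empty cluster")
    scores = {m: tmi(data, m, members) for m in members}
    # max() keeps the first of equal scores; members is sorted ascending, so
    # ties resolve to the lexicographically smallest id
    best = max(members, key=lambda m: scores[m])
    return best, scores


def tmi_table(clusters: Mapping[int, Sequence[str]], data: DiscretizedData) -> pd.DataFrame:
    """Per-cluster TMI listing with the representative flagged."""
    rows = []
    for cid in sorted(clusters):
        rep, scores = select_representative(clusters[cid], data)
        for rid in sorted(scores, key=lambda r: (-scores[r], r)):
            rows.append({"cluster_id": cid, "reaction_id": rid,
                         "tmi_bits": scores[rid], "is_representative": rid == rep})
    return pd.DataFrame(rows, columns=["cluster_id", "reaction_id", "tmi_bits",
                                       "is_representative"])


# ---------------------------------------------------------------------------
# MDL scoring
# ---------------------------------------------------------------------------

class CyclicGraphError(FMBError):
    """A directed graph that must be acyclic contains a cycle."""


def _check_acyclic(parents: Mapping[str, Iterable[str]]) -> None:
    color: dict[str, int] = {}

    def visit(u: str) -> None:
        color[u] = 1
        for p in parents.get(u, ()):
            c = color.get(p, 0)
            if c == 1:
                raise CyclicGraphError(f"cycle through {u!r} and {p!r}")
            if c == 0:
                visit(p)
        color[u] = 2

    for node in parents:
        if color.get(node, 0) == 0:
            visit(node)


def _family_terms(data: DiscretizedData, i: int, parent_rows: Sequence[int]) -> tuple[float, float]:
    """(complexity, codelength) of one node given its parents, in bits."""
    m = data.n_samples
    r = data.cardinalities[i]
    q = 1
    config = np.zeros(m, dtype=np.int64)
    for p in parent_rows:
        config = config * data.cardinalities[p] + data.bins[p]
        q *= data.cardinalities[p]
    complexity = 0.5 * np.log2(m) * q * (r - 1)
    joint = np.bincount(config * r + data.bins[i], minlength=q * r).astype(float)
    parent_tot = joint.reshape(q, r).sum(axis=1)
    nz = joint > 0
    denom = np.repeat(parent_tot, r)
    codelength = -float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))
    return complexity, codelength


def mdl_score(dag: Mapping[str, Iterable[str]], data: DiscretizedData) -> float:
    """MDL score in bits of a DAG over (a subset of) the data's variables.

    Decomposes over families; :class:`CyclicGraphError` on cyclic input.
    """
    parents = {n: tuple(ps) for n, ps in dag.items()}
    _check_acyclic(parents)
    total = 0.0
    for node, ps in parents.items():
        i = data.index(node)
        comp, code = _family_terms(data, i, [data.index(p) for p in ps])
        total += comp + code
    return total


# ---------------------------------------------------------------------------
# Bayesian network container
# ---------------------------------------------------------------------------

@dataclass
class BayesianNetwork:
    nodes: list[str]
    parents: dict[str, tuple[str, ...]]
    score: float
    cpts: dict[str, np.ndarray] = field(default_factory=dict)  # (q_i, r_i), rows sum to 1
    cardinalities: dict[str, int] = field(default_factory=dict)

    @property
    def arcs(self) -> list[tuple[str, str]]:
        return sorted((p, child) for child, ps in self.parents.items() for p in ps)

    @property
    def n_arcs(self) -> int:
        return sum(len(ps) for ps in self.parents.values())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def write_dot(self, path: str | Path) -> None:
        lines = ["digraph bn {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for p, c in self.arcs:
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def _laplace_cpts(parents: Mapping[str, tuple[str, ...]], data: DiscretizedData) -> dict[str, np.ndarray]:
    cpts = {}
    for node, ps in parents.items():
        i = data.index(node)
        r = data.cardinalities[i]
        q = 1
        config = np.zeros(data.n_samples, dtype=np.int64)
        for p in ps:
            j = data.index(p)
            config = config * data.cardinalities[j] + data.bins[j]
            q *= data.cardinalities[j]
        counts = np.bincount(config * r + data.bins[i], minlength=q * r).reshape(q, r)
        smoothed = counts + 1.0
        cpts[node] = smoothed / smoothed.sum(axis=1, keepdims=True)
    return cpts


# ---------------------------------------------------------------------------
# Tabu structure search
# ---------------------------------------------------------------------------

def _random_dag(n: int, rng: np.random.Generator, max_parents: int,
                p_edge: float = 0.25) -> list[set[int]]:
    order = rng.permutation(n)
    parents: list[set[int]] = [set() for _ in range(n)]
    for a in range(n):
        for b in range(a + 1, n):
            u, v = int(order[a]), int(order[b])
            if len(parents[v]) < max_parents and rng.random() < p_edge:
                parents[v].add(u)
    return parents


class _Searcher:
    """One tabu-search run over DAG space with family-score caching."""

    def __init__(self, data: DiscretizedData, max_parents: int, tabu_len: int):
        self.data = data
        self.n = len(data.ids)
        self.max_parents = max_parents
        self.cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self.tabu: deque[tuple] = deque(maxlen=tabu_len)

    def family(self, i: int, parents: frozenset[int] | set[int]) -> float:
        key = (i, tuple(sorted(parents)))
        if key not in self.cache:
            comp, code = _family_terms(self.data, i, key[1])
            self.cache[key] = comp + code
        return self.cache[key]

    def total(self, parents: list[set[int]]) -> float:
        return sum(self.family(i, parents[i]) for i in range(self.n))

    @staticmethod
    def _creates_cycle(parents: list[set[int]], u: int, v: int) -> bool:
        """Would adding u -> v create a cycle (i.e. is v an ancestor of u)?"""
        stack = [u]
        seen = set()
        while stack:
            x = stack.pop()
            if x == v:
                return True
            for p in parents[x]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return False

    def moves(self, parents: list[set[int]]):
        for v in range(self.n):
            for u in range(self.n):
                if u == v:
                    continue
                if u in parents[v]:
                    yield ("del", u, v)
                    if (len(parents[u]) < self.max_parents
                            and not self._rev_creates_cycle(parents, u, v)):
                        yield ("rev", u, v)
                elif (len(parents[v]) < self.max_parents
                      and not self._creates_cycle(parents, u, v)):
                    yield ("add", u, v)

    def _rev_creates_cycle(self, parents: list[set[int]], u: int, v: int) -> bool:
        parents[v].discard(u)
        bad = self._creates_cycle(parents, v, u)
        parents[v].add(u)
        return bad

    def delta(self, parents: list[set[int]], move: tuple) -> float:
        op, u, v = move
        if op == "add":
            return self.family(v, parents[v] | {u}) - self.family(v, parents[v])
        if op == "del":
            return self.family(v, parents[v] - {u}) - self.family(v, parents[v])
        return (self.family(v, parents[v] - {u}) - self.family(v, parents[v])
                + self.family(u, parents[u] | {v}) - self.family(u, parents[u]))

    @staticmethod
    def apply(parents: list[set[int]], move: tuple) -> None:
        op, u, v = move
        if op == "add":
            parents[v].add(u)
        elif op == "del":
            parents[v].discard(u)
        else:
            parents[v].discard(u)
            parents[u].add(v)

    @staticmethod
    def inverse(move: tuple) -> tuple:
        op, u, v = move
        if op == "add":
            return ("del", u, v)
        if op == "del":
            return ("add", u, v)
        return ("rev", v, u)

    def run(self, start: list[set[int]], max_iter: int) -> tuple[list[set[int]], float]:
        parents = [set(s) for s in start]
        score = self.total(parents)
        best = [set(s) for s in parents]
        best_score = score
        self.tabu.clear()
        for _ in range(max_iter):
            candidates = []
            for move in self.moves(parents):
                d = self.delta(parents, move)
                # aspiration: a tabu move is allowed if it beats the best ever
                if move in self.tabu and score + d >= best_score - 1e-12:
                    continue
                candidates.append((d, move))
            if not candidates:
                break
            d, move = min(candidates, key=lambda c: (c[0], c[1]))
            self.apply(parents, move)
            score += d
            self.tabu.append(self.inverse(move))
            if score < best_score - 1e-12:
                best_score = score
                best = [set(s) for s in parents]
        return best, best_score


def tabu_learn(data: DiscretizedData, max_iter: int = 100, tabu_len: int = 10,
               seed: int = 0, restarts: int = 3, max_parents: int = 4) -> BayesianNetwork:
    """Learn a DAG by MDL-scored tabu search with random restarts.

    The first restart starts from the empty graph; later restarts from random
    DAGs. The best DAG ever visited (by MDL, lower is better) is returned,
    deterministically under a fixed seed.
    """
    if len(data.ids) < 2:
        raise ValueError("structure learning needs at least 2 variables")
    rng = np.random.default_rng(seed)
    searcher = _Searcher(data, max_parents, tabu_len)
    n = len(data.ids)
    best_parents: list[set[int]] | None = None
    best_score = np.inf
    for r in range(max(1, restarts)):
        start = ([set() for _ in range(n)] if r == 0
                 else _random_dag(n, rng, max_parents))
        parents, score = searcher.run(start, max_iter)
        if score < best_score - 1e-12:
            best_score = score
            best_parents = parents
    assert best_parents is not None
    name_parents = {
        data.ids[v]: tuple(sorted(data.ids[u] for u in best_parents[v]))
        for v in range(n)
    }
    return BayesianNetwork(
        nodes=list(data.ids), parents=name_parents, score=float(best_score),
        cpts=_laplace_cpts(name_parents, data),
        cardinalities=dict(zip(data.ids, data.cardinalities)),
    )


# ---------------------------------------------------------------------------
# Local / global networks
# ---------------------------------------------------------------------------

def learn_local_bns(clusters: Mapping[int, Sequence[str]], data: DiscretizedData,
                    seed: int = 0, **tabu_kwargs) -> dict[int, BayesianNetwork]:
    """One network per module; singleton modules get a trivial one-node net."""
    out: dict[int, BayesianNetwork] = {}
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        sub = data.restrict(members)
        if len(members) < 2:
            parents = {members[0]: ()}
            out[cid] = BayesianNetwork(
                members, parents, mdl_score(parents, sub),
                _laplace_cpts(parents, sub),
                {members[0]: sub.cardinalities[0]},
            )
        else:
            out[cid] = tabu_learn(sub, seed=seed + cid, **tabu_kwargs)
    return out


def learn_global_bn(representatives: Sequence[str], data: DiscretizedData,
                    seed: int = 0, **tabu_kwargs) -> BayesianNetwork:
    """Network over module representatives: causal influence among modules."""
    sub = data.restrict(sorted(representatives))
    return tabu_learn(sub, seed=seed, **tabu_kwargs)


def exhaustive_search(data: DiscretizedData) -> tuple[dict[str, tuple[str, ...]], float]:
    """Exact MDL-optimal DAG by enumeration (tiny variable counts only)."""
    ids = list(data.ids)
    n = len(ids)
    if n > 4:
        raise ValueError("exhaustive enumeration limited to <= 4 variables")
    pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
    best_score = np.inf
    best: dict[str, tuple[str, ...]] | None = None
    for mask in range(1 << len(pairs)):
        parents: dict[str, list[str]] = {i: [] for i in ids}
        ok = True
        for b, (u, v) in enumerate(pairs):
            if mask >> b & 1:
                if mask >> pairs.index((v, u)) & 1:  # 2-cycle shortcut
                    ok = False
                    break
                parents[ids[v]].append(ids[u])
        if not ok:
            continue
        dag = {k: tuple(vs) for k, vs in parents.items()}
        try:
            score = mdl_score(dag, data)
        except CyclicGraphError:
            continue
        if score < best_score - 1e-12:
            best_score = score
            best = dag
    assert best is not None
    return best, float(best_score)
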