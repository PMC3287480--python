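import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from fmb.modularization import (
    build_adjoined_pattern,
    cluster_core_reactions,
    hierarchical_cluster,
    pattern_distances,
    reinsert_duplicates,
    to_flux_pattern,
)


def sign_oracle(values, permutation, tol=1e-6):
    ordered = np.asarray(values, float)[:, list(permutation)]
    out = np.zeros((ordered.shape[0], ordered.shape[1] - 1), dtype=int)
    for n in range(ordered.shape[0]):
        for m in range(ordered.shape[1] - 1):
            d = ordered[n, m + 1] - ordered[n, m]
            out[n, m] = 1 if d > tol else (-1 if d < -tol else 0)
    return out


class TestFluxPattern:
    def test_constant_row_all_zeros(self):
        assert np.all(to_flux_pattern(np.ones((1, 6))) == 0)

    def test_sign_of_consecutive_differences(self):
        assert to_flux_pattern(np.array([[1.0, 3.0, 2.0]])).tolist() == [[1, -1]]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(2, 6), st.integers(2, 8), st.integers(0, 10_000))
    def test_matches_sign_oracle_with_ties(self, n, m, seed):
        rng = np.random.default_rng(seed)
        # quantized values create genuine ties
        values = np.round(rng.normal(size=(n, m)), 1)
        perm = rng.permutation(m)
        assert np.array_equal(to_flux_pattern(values, perm), sign_oracle(values, perm))

    def test_reversed_permutation_negates_and_reverses(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(3, 9))  # continuous -> tie-free
        perm = rng.permutation(9)
        fwd = to_flux_pattern(values, perm)
        rev = to_flux_pattern(values, perm[::-1])
        assert np.array_equal(rev, -fwd[:, ::-1])

    def test_non_bijective_permutation_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            to_flux_pattern(np.ones((1, 3)), [0, 0, 2])


class TestAdjoined:
    def test_identity_permutation_reduces_to_single_pattern(self):
        values = np.random.default_rng(0).normal(size=(4, 7))
        adj = build_adjoined_pattern(values, permutations=[np.arange(7)])
        assert np.array_equal(adj, to_flux_pattern(values))

    def test_width_arithmetic(self):
        values = np.random.default_rng(1).normal(size=(3, 11))
        adj = build_adjoined_pattern(values, n_perms=20, seed=2)
        assert adj.shape == (3, 20 * 10)

    def test_duplicate_rows_stay_identical(self):
        row = np.random.default_rng(2).normal(size=10)
        adj = build_adjoined_pattern(np.vstack([row, row]), n_perms=5, seed=3)
        assert np.array_equal(adj[0], adj[1])

    def test_blockwise_distances_equal_naive_construction(self):
        values = np.random.default_rng(4).normal(size=(6, 15))
        naive = pdist(build_adjoined_pattern(values, n_perms=12, seed=9).astype(float))
        blockwise = pattern_distances(values, n_perms=12, seed=9)
        assert np.allclose(blockwise, naive, atol=1e-10)


def naive_average_linkage(values):
    """O(n^3) agglomerative average linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(values))]
    d = np.sqrt(((values[:, None, :] - values[None, :, :]) ** 2).sum(-1))
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if avg < best[0]:
                    best = (avg, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


class TestClustering:
    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            values = rng.normal(size=(rng.integers(3, 9), 6))
            from scipy.cluster.hierarchy import linkage

            Z = linkage(pdist(values), method="average")
            assert np.allclose(np.sort(Z[:, 2]), np.sort(naive_average_linkage(values)))

    def test_identical_rows_share_a_cluster(self):
        row = np.random.default_rng(0).normal(size=30)
        other = np.random.default_rng(1).normal(size=(4, 30))
        patterns = np.vstack([row, row, other])
        a = hierarchical_cluster(patterns, [f"R{i}" for i in range(6)])
        assert a.labels["R0"] == a.labels["R1"]

    def test_single_row_is_one_singleton(self):
        a = hierarchical_cluster(np.ones((1, 5)), ["R0"])
        assert a.labels == {"R0": 1}

    def test_merge_heights_monotone(self, toy_core):
        a = cluster_core_reactions(toy_core.reduced_matrix.values,
                                   toy_core.core_reaction_ids, n_perms=5, seed=1)
        heights = a.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_row_order_invariance_up_to_renumbering(self):
        rng = np.random.default_rng(21)
        patterns = np.vstack([np.tile(rng.choice([-1, 1], size=40), (3, 1)) + 0.0
                              for _ in range(3)])
        patterns += rng.normal(scale=1e-3, size=patterns.shape)
        ids = [f"R{i}" for i in range(9)]
        a = hierarchical_cluster(patterns, ids)
        order = rng.permutation(9)
        b = hierarchical_cluster(patterns[order], [ids[i] for i in order])
        # same partition of ids, possibly different numbering
        part_a = {frozenset(a.members(c)) for c in set(a.labels.values())}
        part_b = {frozenset(b.members(c)) for c in set(b.labels.values())}
        assert part_a == part_b

    def test_cluster_ids_are_1_to_C_by_first_row(self, toy_core):
        a = cluster_core_reactions(toy_core.reduced_matrix.values,
                                   toy_core.core_reaction_ids, n_perms=5, seed=1)
        labels = [a.labels[r] for r in toy_core.core_reaction_ids]
        seen = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == list(range(1, a.n_clusters + 1))


class TestReinsertion:
    def test_empty_map_is_identity(self, toy_core):
        a = cluster_core_reactions(toy_core.reduced_matrix.values,
                                   toy_core.core_reaction_ids, n_perms=5, seed=1)
        assert reinsert_duplicates(a, {}).labels == a.labels

    def test_members_join_representative_cluster(self, toy_core):
        a = cluster_core_reactions(toy_core.reduced_matrix.values,
                                   toy_core.core_reaction_ids, n_perms=5, seed=1)
        full = reinsert_duplicates(a, toy_core.duplicate_groups)
        for rep, members in toy_core.duplicate_groups.items():
            for m in members:
                assert full.labels[m] == full.labels[rep]
        n_dups = sum(len(v) for v in toy_core.duplicate_groups.values())
        assert len(full.labels) == len(a.labels) + n_dups

    def test_orphan_representative_rejected(self, toy_core):
        a = cluster_core_reactions(toy_core.reduced_matrix.values,
                                   toy_core.core_reaction_ids, n_perms=5, seed=1)
        with pytest.raises(KeyError, match="GHOST"):
            reinsert_duplicates(a, {"GHOST": ["R1"]})


class TestModuleRecovery:
    def test_toy_modules_recovered_exactly(self, toy_fixture, toy_core):
        from sklearn.metrics import adjusted_rand_score

        a = cluster_core_reactions(toy_core.reduced_matrix.values,
                                   toy_core.core_reaction_ids, n_perms=20, seed=0)
        full = reinsert_duplicates(a, toy_core.duplicate_groups)
        truth = toy_fixture.module_of
        ids = sorted(truth)
        ari = adjusted_rand_score([truth[r] for r in ids],
                                  [full.labels[r] for r in ids])
        assert ari == 1.0

    def test_partition_consistent_across_permutation_seeds(self, toy_core):
        parts = []
        for seed in (1, 2):
            a = cluster_core_reactions(toy_core.reduced_matrix.values,
                                       toy_core.core_reaction_ids,
                                       n_perms=20, seed=seed)
            parts.append({frozenset(a.members(c)) for c in set(a.labels.values())})
        assert parts[0] == parts[1]
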