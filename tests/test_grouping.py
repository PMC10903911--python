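"""Ward clustering, dendrogram cuts, and the indistinguishable-group merge rule.

The Ward oracle here recomputes the merge sequence from raw coordinates by
greedy minimization of the within-cluster sum-of-squares increase
(Delta-ESS), entirely independent of the Lance-Williams distance-update
path used by the implementation; linkage heights satisfy h^2 = 2 * Delta-ESS.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isofoodweb.grouping import (
    cut_to_groups,
    isotope_distance_matrix,
    merge_indistinguishable,
    pool_summaries,
    ward_cluster,
)
from conftest import make_group, make_sample


def brute_force_ward_heights(X):
    """Greedy Ward merging straight from coordinates; returns sorted heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d_ess = na * nb / (na + nb) * ((ca - cb) ** 2).sum()
                if best is None or d_ess < best[0]:
                    best = (d_ess, a, b)
        d_ess, a, b = best
        heights.append(np.sqrt(2.0 * d_ess))
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return np.sort(heights)


def euclidean(X):
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


class TestDistanceMatrix:
    def test_identical_samples_have_zero_distance(self):
        s = [make_sample("a", -20.0, 5.0), make_sample("b", -20.0, 5.0)]
        d = isotope_distance_matrix(s, ["d13C", "d15N"])
        assert np.allclose(d, 0.0)

    def test_single_axis_difference(self):
        s = [make_sample("a", -20.0, 5.0), make_sample("b", -17.0, 5.0)]
        d = isotope_distance_matrix(s, ["d13C", "d15N"])
        assert d[0, 1] == pytest.approx(3.0)

    def test_three_four_five_triangle(self):
        s = [make_sample("a", 0.0, 0.0), make_sample("b", 3.0, 4.0)]
        d = isotope_distance_matrix(s, ["d13C", "d15N"])
        assert d[0, 1] == pytest.approx(5.0)

    def test_missing_isotope_names_sample(self):
        s = [make_sample("nosulfur", -20.0, 5.0, None)]
        with pytest.raises(ValueError, match="nosulfur"):
            isotope_distance_matrix(s, ["d13C", "d15N", "d34S"])

    def test_symmetric_zero_diagonal(self, rng):
        s = [make_sample(f"s{i}", *rng.normal(size=2)) for i in range(6)]
        d = isotope_distance_matrix(s, ["d13C", "d15N"])
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestWardCluster:
    def test_two_identical_points_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        dend = ward_cluster(euclidean(X))
        assert dend.heights[0] == pytest.approx(0.0)

    def test_two_tight_clusters_merge_within_before_between(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        dend = ward_cluster(euclidean(X), leaf_ids=list("abcd"))
        # first two merges join the planted pairs, the last spans clusters
        merged_pairs = {frozenset(m[:2]) for m in dend.merges[:2]}
        assert merged_pairs == {frozenset({0, 1}), frozenset({2, 3})}
        assert dend.heights[2] > 9.0

    def test_requires_two_leaves(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((1, 1)))

    @given(st.integers(0, 9999))
    @settings(max_examples=25, deadline=None)
    def test_heights_match_brute_force_oracle(self, seed):
        """Linkage heights equal exhaustive Delta-ESS Ward on <= 6 leaves."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        X = rng.normal(scale=3.0, size=(n, 2))
        dend = ward_cluster(euclidean(X))
        np.testing.assert_allclose(np.sort(dend.heights),
                                   brute_force_ward_heights(X), rtol=1e-9)

    def test_riverine_vs_delta_plants_separate_at_two_groups(
            self, fixture_table):
        riverine = fixture_table.source("S6")
        delta = fixture_table.source("S9")
        members = fixture_table.source_members
        rows = members[members.group_id.isin(["S6", "S9"])]
        X = rows[["d13C_mean", "d15N_mean"]].to_numpy()
        leaf_ids = [f"{gid}:{i}" for i, gid in enumerate(rows.group_id)]
        dend = ward_cluster(euclidean(X), leaf_ids=leaf_ids)
        labels = cut_to_groups(dend, 2)
        by_group = {}
        for leaf, lbl in labels.items():
            by_group.setdefault(leaf.split(":")[0], set()).add(lbl)
        assert by_group["S6"].isdisjoint(by_group["S9"])
        assert riverine.means["d13C"] < delta.means["d13C"]

    def test_order_invariance_of_heights(self, rng):
        X = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        h1 = np.sort(ward_cluster(euclidean(X)).heights)
        h2 = np.sort(ward_cluster(euclidean(X[perm])).heights)
        np.testing.assert_allclose(h1, h2, rtol=1e-9)

    def test_newick_round_trips_leaf_names(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0]])
        dend = ward_cluster(euclidean(X), leaf_ids=["apple", "pear", "plum"])
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for name in ("apple", "pear", "plum"):
            assert name in nwk


class TestCutToGroups:
    @pytest.fixture
    def toy_dend(self):
        X = np.array([[0.0, 0.0], [0.2, 0.0], [8.0, 0.0], [8.3, 0.0]])
        return ward_cluster(euclidean(X), leaf_ids=list("abcd"))

    def test_k_equals_n_singletons(self, toy_dend):
        labels = cut_to_groups(toy_dend, 4)
        assert len(set(labels.values())) == 4

    def test_k_one_single_group(self, toy_dend):
        labels = cut_to_groups(toy_dend, 1)
        assert set(labels.values()) == {0}

    def test_recovers_planted_clusters(self, toy_dend):
        labels = cut_to_groups(toy_dend, 2)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_partition_covers_all_leaves(self, toy_dend):
        for k in (1, 2, 3, 4):
            labels = cut_to_groups(toy_dend, k)
            assert set(labels) == set("abcd")
            assert len(set(labels.values())) == k

    @pytest.mark.parametrize("k", [0, 5])
    def test_k_out_of_range(self, toy_dend, k):
        with pytest.raises(ValueError):
            cut_to_groups(toy_dend, k)


class TestMergeIndistinguishable:
    def test_identical_groups_merge(self):
        a = make_group("a", 6, {"d13C": -21.0, "d15N": 6.0})
        b = make_group("b", 6, {"d13C": -21.0, "d15N": 6.0})
        merged, log = merge_indistinguishable([a, b], ["d13C", "d15N"])
        assert len(merged) == 1
        assert len(log) == 1

    def test_distant_groups_untouched(self):
        a = make_group("a", 6, {"d13C": -30.0, "d15N": 0.0})
        b = make_group("b", 6, {"d13C": -10.0, "d15N": 10.0})
        merged, log = merge_indistinguishable([a, b], ["d13C", "d15N"])
        assert len(merged) == 2
        assert log == []

    def test_macroalgae_and_eelgrass_combine_into_delta_plants(
            self, fixture_table):
        """On d13C/d15N alone, Ulva and eelgrass cannot be told apart."""
        members = fixture_table.source_members
        rows = members[members.group_id == "S9"]
        groups = [
            make_group(f"{r.member}|{r.habitat}", int(r.n),
                       {"d13C": r.d13C_mean, "d15N": r.d15N_mean},
                       {"d13C": r.d13C_sd, "d15N": r.d15N_sd})
            for r in rows.itertuples(index=False)
        ]
        merged, log = merge_indistinguishable(groups, ["d13C", "d15N"])
        assert len(merged) == 1       # a single "delta plants" source
        assert merged[0].n == sum(g.n for g in groups)

    def test_merge_conserves_total_n(self):
        groups = [make_group(f"g{i}", 4 + i, {"d13C": -20.0 + 0.05 * i})
                  for i in range(4)]
        merged, _ = merge_indistinguishable(groups, ["d13C"])
        assert sum(g.n for g in merged) == sum(4 + i for i in range(4))

    def test_requires_requested_isotopes(self):
        a = make_group("a", 3, {"d13C": -20.0})
        with pytest.raises(ValueError, match="d15N"):
            merge_indistinguishable([a, a], ["d13C", "d15N"])


class TestPoolSummaries:
    def test_pooled_moments_equal_concatenated_sample_moments(self, rng):
        xa = rng.normal(-20, 2, size=8)
        xb = rng.normal(-15, 1, size=5)
        a = make_group("a", 8, {"d13C": xa.mean()},
                       {"d13C": xa.std(ddof=1)})
        b = make_group("b", 5, {"d13C": xb.mean()},
                       {"d13C": xb.std(ddof=1)})
        pooled = pool_summaries([a, b], "ab", "ab", ["d13C"])
        allx = np.concatenate([xa, xb])
        assert pooled.n == 13
        assert pooled.means["d13C"] == pytest.approx(allx.mean())
        assert pooled.sds["d13C"] == pytest.approx(allx.std(ddof=1))
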