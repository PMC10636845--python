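"""Merge machinery, full agglomeration, and cluster-number selection."""

import numpy as np
import pytest

from tsclust.data import TsclustError
from tsclust.hierarchy import (agglomerate, cluster_cell_distance,
                               cluster_cluster_distance, merge_cost,
                               partition_sigma, select_k)
from tsclust.simulate import SyntheticSpec, generate
from tsclust.model import TSC
from tsclust.walk import rw_distance

from conftest import profile_from_weights, two_clique_weights


@pytest.fixture
def profile(rng):
    w = rng.random((8, 8)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
    return profile_from_weights(w)


class TestClusterDistances:
    def test_literal_singleton_is_raw_probability(self, profile):
        assert cluster_cell_distance([2], 5, profile, "literal") == profile.probs[2, 5]

    def test_literal_pair_is_arithmetic_mean(self, profile):
        expect = (profile.probs[1, 4] + profile.probs[3, 4]) / 2
        assert cluster_cell_distance([1, 3], 4, profile, "literal") == pytest.approx(expect)

    def test_walktrap_cell_in_own_singleton_is_zero(self, profile):
        assert cluster_cell_distance([3], 3, profile, "walktrap") == 0.0

    def test_singleton_cluster_distance_is_rw_distance(self, profile):
        d = rw_distance(profile)
        for i, j in [(0, 1), (2, 5), (4, 7)]:
            assert cluster_cluster_distance([i], [j], profile) == pytest.approx(d[i, j])

    def test_identical_singletons_distance_zero(self, profile):
        assert cluster_cluster_distance([2], [2], profile) == 0.0

    def test_two_pair_clusters_match_term_sum(self, profile):
        ci, cj = [0, 1], [2, 3]
        di = profile.probs[ci].mean(axis=0)
        dj = profile.probs[cj].mean(axis=0)
        expect = np.sqrt(np.sum((di - dj) ** 2 / profile.degrees))
        assert cluster_cluster_distance(ci, cj, profile) == pytest.approx(expect)

    def test_overlapping_clusters_rejected(self, profile):
        with pytest.raises(TsclustError, match="overlap"):
            cluster_cluster_distance([0, 1], [1, 2], profile)

    def test_empty_cluster_rejected(self, profile):
        with pytest.raises(TsclustError, match="empty"):
            cluster_cell_distance([], 0, profile)


class TestMergeCost:
    @pytest.mark.parametrize("mode", ["walktrap", "literal"])
    def test_equals_sigma_difference(self, profile, mode):
        """Merge cost must equal the from-scratch sigma change."""
        ci, cj, rest = [0, 1], [2, 3, 4], [[5], [6, 7]]
        before = partition_sigma([ci, cj, *rest], profile, mode)
        after = partition_sigma([ci + cj, *rest], profile, mode)
        assert merge_cost(ci, cj, profile, mode) == pytest.approx(
            after - before, abs=1e-10)

    def test_automorphic_merges_cost_the_same(self):
        w = two_clique_weights(3)
        p = profile_from_weights(w)
        # (0,1) and (4,5) are equivalent under the graph automorphism
        assert merge_cost([0], [1], p) == pytest.approx(merge_cost([4], [5], p))

    def test_self_merge_rejected(self, profile):
        with pytest.raises(TsclustError):
            merge_cost([0, 1], [1], profile)

    def test_nearest_planted_subclusters_cheapest(self):
        w = two_clique_weights(3, strong=1.0, weak=0.05)
        p = profile_from_weights(w)
        costs = {(i, j): merge_cost([i], [j], p)
                 for i in range(6) for j in range(i + 1, 6)}
        best = min(costs, key=costs.get)
        within = best[0] < 3 and best[1] < 3 or best[0] >= 3 and best[1] >= 3
        assert within


class TestAgglomerate:
    def test_two_cells_single_merge(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        state = agglomerate(profile_from_weights(w, t=2))
        assert len(state.merge_trace) == 1
        np.testing.assert_array_equal(state.labels_at(1), [1, 1])
        np.testing.assert_array_equal(state.labels_at(2), [1, 2])

    @pytest.mark.parametrize("mode", ["walktrap", "literal"])
    def test_every_merge_matches_brute_force_sigma(self, mode, rng):
        """Replay a 10-cell run, recomputing sigma from scratch at each level."""
        w = rng.random((10, 10)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        p = profile_from_weights(w)
        state = agglomerate(p, mode=mode)
        clusters = [[i] for i in range(10)]
        sigma_prev = partition_sigma(clusters, p, mode)
        assert state.sigma_history[10] == pytest.approx(sigma_prev, abs=1e-10)
        for level, (a, b, dsigma) in zip(range(10, 1, -1), state.merge_trace):
            ca = next(c for c in clusters if min(c) == a)
            cb = next(c for c in clusters if min(c) == b)
            # recorded cost equals the definitionally-evaluated merge cost
            assert dsigma == pytest.approx(merge_cost(ca, cb, p, mode), abs=1e-10)
            clusters.remove(ca); clusters.remove(cb); clusters.append(sorted(ca + cb))
            sigma_now = partition_sigma(clusters, p, mode)
            assert state.sigma_history[level - 1] == pytest.approx(sigma_now, abs=1e-10)

    @pytest.mark.parametrize("mode", ["walktrap", "literal"])
    def test_greedy_choice_is_globally_minimal(self, mode, rng):
        """The first merge is the cheapest over all pairs (exhaustive check)."""
        w = rng.random((9, 9)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        p = profile_from_weights(w)
        state = agglomerate(p, mode=mode)
        a, b, dsigma = state.merge_trace[0]
        all_costs = [merge_cost([i], [j], p, mode)
                     for i in range(9) for j in range(i + 1, 9)]
        assert dsigma == pytest.approx(min(all_costs), abs=1e-12)

    def test_two_triangles_merge_within_first(self):
        w = two_clique_weights(3, strong=1.0, weak=0.05)
        state = agglomerate(profile_from_weights(w))
        for a, b, _ in state.merge_trace[:3]:
            assert (a < 3) == (b < 3)  # both endpoints in the same triangle
        np.testing.assert_array_equal(state.labels_at(2), [1, 1, 1, 2, 2, 2])

    def test_sigma_monotone_in_walktrap_mode(self, rng):
        w = rng.random((12, 12)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        state = agglomerate(profile_from_weights(w))
        sig = state.sigma_history[1:13]
        assert np.all(np.diff(sig) <= 1e-15)  # non-increasing as K grows

    def test_permutation_equivariance(self, rng):
        from tsclust.metrics import adjusted_rand_index
        w = rng.random((10, 10)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        perm = rng.permutation(10)
        labels = agglomerate(profile_from_weights(w)).labels_at(3)
        labels_p = agglomerate(profile_from_weights(w[np.ix_(perm, perm)])).labels_at(3)
        assert adjusted_rand_index(labels[perm], labels_p) == 1.0


class TestSelectK:
    def test_two_clique_graph_selects_two(self):
        w = two_clique_weights(5, strong=1.0, weak=0.05)
        state = agglomerate(profile_from_weights(w))
        assert select_k(state) == 2

    @pytest.mark.parametrize("k_true", [2, 3, 4, 5, 6])
    def test_recovers_planted_k(self, k_true):
        x, _ = generate(SyntheticSpec(n_cells=150, n_genes=120, k_true=k_true,
                                      separation=6, seed=k_true))
        res = TSC(x).fit()
        assert res.k == k_true

    def test_degenerate_plateau_falls_back_to_k_min(self):
        # every cell has the identical walk profile: all merge costs are 0,
        # sigma is flat, and the jump ratio carries no signal at any level
        from tsclust.walk import WalkProfile
        row = np.full(6, 1 / 6)
        p = WalkProfile(probs=np.tile(row, (6, 1)), degrees=np.ones(6), t=4)
        state = agglomerate(p)
        with pytest.warns(UserWarning):
            k = select_k(state)
        assert k == 2

    def test_fixed_range_validation(self, rng):
        w = rng.random((6, 6)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        state = agglomerate(profile_from_weights(w))
        with pytest.raises(TsclustError):
            select_k(state, k_min=5, k_max=3)
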