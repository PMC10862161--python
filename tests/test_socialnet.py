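"""Grouping, SRI networks and network/node metrics."""

import numpy as np
import pandas as pd
import pytest

from flocknet import (
    GbiMatrix,
    SriNetwork,
    association_threshold,
    cv_edge_weights,
    density,
    gbi_by_window,
    group_fixes,
    modularity,
    node_metrics,
    partition_modularity,
    sri_network,
)

from conftest import make_grid


def net_from_weights(w):
    w = np.asarray(w, float)
    n = len(w)
    ids = [f"s{k}" for k in range(n)]
    together = (w * 10).astype(int)
    both = np.full((n, n), 10, int)
    np.fill_diagonal(both, 0)
    return SriNetwork(ids, w, together, both)


class TestAssociationThreshold:
    @pytest.mark.parametrize(
        "body, acc, expected",
        [(1.0, 2.0, 5.0), (1.0, 0.0, 1.0), (0.5, 1.67, 3.84)],
    )
    def test_body_plus_two_accuracies(self, body, acc, expected):
        assert association_threshold(body, acc) == pytest.approx(expected)

    def test_rejects_nonpositive_body(self):
        with pytest.raises(ValueError):
            association_threshold(0.0, 2.0)


class TestGrouping:
    def test_chain_rule_links_transitively(self):
        # A-B and B-C within 5 m, A-C 8 m apart: one group of three
        pos = np.array([[[0.0, 0.0]], [[4.0, 0.0]], [[8.0, 0.0]]])
        gbi = group_fixes(make_grid(pos), threshold=5.0)
        assert gbi.matrix.shape == (1, 3)
        assert gbi.matrix.sum() == 3

    def test_distant_pair_stays_singletons(self):
        pos = np.array([[[0.0, 0.0]], [[6.0, 0.0]]])
        gbi = group_fixes(make_grid(pos), threshold=5.0)
        assert gbi.matrix.shape == (2, 2)
        assert (gbi.matrix.sum(axis=1) == 1).all()

    def test_all_apart_gives_all_singletons(self):
        n = 12
        pos = np.zeros((n, 1, 2))
        pos[:, 0, 0] = np.arange(n) * 50.0
        gbi = group_fixes(make_grid(pos), threshold=5.0)
        assert gbi.matrix.shape == (n, n)

    def test_absent_individuals_skipped(self):
        pos = np.zeros((2, 2, 2))
        present = np.array([[True, True], [False, True]])
        pos[1, 0] = np.nan
        gbi = group_fixes(make_grid(pos, present=present), threshold=5.0)
        # instant 0 has one singleton, instant 1 one pair
        assert gbi.matrix.shape == (2, 2)
        assert gbi.present.sum() == 3

    def test_double_membership_rejected(self):
        m = np.array([[1, 1], [1, 0]], np.uint8)
        with pytest.raises(ValueError, match="two groups"):
            GbiMatrix(["a", "b"], m, np.zeros(2, int), np.ones((2, 1), bool))


class TestSri:
    def test_constant_companions_score_one(self):
        pos = np.zeros((2, 90, 2))
        pos[1, :, 0] = 3.0
        net = sri_network(group_fixes(make_grid(pos), 5.0))
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_half_time_dyad(self):
        # together at 2 of 4 co-recorded instants
        pos = np.zeros((2, 4, 2))
        pos[1, :, 0] = [3.0, 3.0, 50.0, 50.0]
        net = sri_network(group_fixes(make_grid(pos), 5.0))
        assert net.weights[0, 1] == pytest.approx(0.5)
        assert net.together[0, 1] == 2
        assert net.both_recorded[0, 1] == 4

    def test_never_corecorded_is_zero(self):
        pos = np.zeros((2, 2, 2))
        present = np.array([[True, False], [False, True]])
        pos[0, 1] = np.nan
        pos[1, 0] = np.nan
        net = sri_network(group_fixes(make_grid(pos, present=present), 5.0))
        assert net.weights[0, 1] == 0.0
        assert net.both_recorded[0, 1] == 0

    def test_agrees_with_per_instant_bruteforce(self):
        """Chain grouping + SRI vs an independent per-instant oracle."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(17)
        threshold = 5.0
        for _ in range(10):
            n_ind, n_inst = 6, 20
            pos = rng.uniform(0, 25, size=(n_ind, n_inst, 2))
            present = rng.uniform(size=(n_ind, n_inst)) < 0.8
            pos[~present] = np.nan
            grid = make_grid(pos, present=present)
            net = sri_network(group_fixes(grid, threshold))

            together = np.zeros((n_ind, n_ind))
            both = np.zeros((n_ind, n_ind))
            for t in range(n_inst):
                here = np.flatnonzero(present[:, t])
                for a in range(len(here)):
                    for b in range(a + 1, len(here)):
                        i, j = here[a], here[b]
                        both[i, j] += 1
                        both[j, i] += 1
                if len(here) < 2:
                    continue
                lab = fcluster(
                    linkage(pdist(pos[here, t]), method="single"),
                    t=threshold,
                    criterion="distance",
                )
                for a in range(len(here)):
                    for b in range(a + 1, len(here)):
                        if lab[a] == lab[b]:
                            i, j = here[a], here[b]
                            together[i, j] += 1
                            together[j, i] += 1
            expect = np.where(both > 0, together / np.maximum(both, 1), 0.0)
            np.testing.assert_allclose(net.weights, expect, atol=1e-12)
            np.testing.assert_allclose(net.together, together)
            np.testing.assert_allclose(net.both_recorded, both)


class TestDensity:
    def test_complete_graph(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0)
        assert density(net_from_weights(w)) == 1.0

    def test_edgeless_graph(self):
        assert density(net_from_weights(np.zeros((4, 4)))) == 0.0

    def test_path_on_three_nodes(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.2
        assert density(net_from_weights(w)) == pytest.approx(2 / 3)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            density(net_from_weights(np.zeros((1, 1))))


def two_triangles():
    w = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[i, j] = w[j, i] = 1.0
    return net_from_weights(w)


class TestModularity:
    def test_two_disconnected_triangles(self):
        # Q = sum_c (e_c - a_c^2) = 2 x (0.5 - 0.25) = 0.5
        q, parts = modularity(two_triangles(), return_partition=True)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert sorted(sorted(p) for p in parts) == [
            ["s0", "s1", "s2"],
            ["s3", "s4", "s5"],
        ]

    def test_single_community_partition_scores_zero(self):
        net = two_triangles()
        q = partition_modularity(net, [set(net.ids)])
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_greedy_beats_trivial_partition(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            w = np.triu(rng.uniform(size=(8, 8)) < 0.4, 1) * rng.uniform(
                0.1, 1, (8, 8)
            )
            w = w + w.T
            net = net_from_weights(w)
            if (w > 0).sum() == 0:
                continue
            assert modularity(net) >= -1e-12

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            modularity(net_from_weights(np.zeros((3, 3))))


class TestCvEdgeWeights:
    def test_equal_weights_give_zero(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0)
        assert cv_edge_weights(net_from_weights(w)) == pytest.approx(0.0)

    def test_two_edge_universe(self):
        # weights {0.1, 0.3}: sd = 0.1*sqrt(2), mean 0.2 -> CV = 0.7071
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.1
        w[1, 2] = w[2, 1] = 0.3
        cv = cv_edge_weights(net_from_weights(w), nonzero_only=True)
        assert cv == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_zero_dyads_included_by_default(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.1
        w[1, 2] = w[2, 1] = 0.3
        vals = np.array([0.1, 0.3, 0.0])
        expect = vals.std(ddof=1) / vals.mean()
        assert cv_edge_weights(net_from_weights(w)) == pytest.approx(expect)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cv_edge_weights(net_from_weights(np.zeros((3, 3))))


class TestNodeMetrics:
    def test_star_graph(self):
        w = np.zeros((4, 4))
        for leaf in (1, 2, 3):
            w[0, leaf] = w[leaf, 0] = 1.0
        nm = node_metrics(net_from_weights(w)).set_index("id")
        assert nm.loc["s0", "degree"] == 3
        assert nm.loc["s1", "degree"] == 1
        # all 3 leaf pairs route through the centre
        assert nm.loc["s0", "betweenness"] == pytest.approx(3.0)
        assert nm.loc["s1", "betweenness"] == pytest.approx(0.0)

    def test_isolated_node_zeroes(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        nm = node_metrics(net_from_weights(w)).set_index("id")
        assert nm.loc["s2", "degree"] == 0
        assert nm.loc["s2", "strength"] == 0.0
        assert nm.loc["s2", "betweenness"] == 0.0

    def test_strength_bounded_by_degree(self):
        rng = np.random.default_rng(4)
        w = np.triu(rng.uniform(size=(10, 10)) < 0.5, 1) * rng.uniform(
            0, 1, (10, 10)
        )
        w = w + w.T
        nm = node_metrics(net_from_weights(w))
        assert (nm["strength"] <= nm["degree"] + 1e-12).all()

    def test_betweenness_prefers_strong_routes(self):
        # path 0-1-2 with strong edges vs a weak direct 0-2 edge:
        # the two-hop route is shorter in 1/weight length
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.9
        w[0, 2] = w[2, 0] = 0.1
        nm = node_metrics(net_from_weights(w)).set_index("id")
        assert nm.loc["s1", "betweenness"] == pytest.approx(1.0)


class TestGbiByWindow:
    def test_splits_days(self, small_dataset, small_grid):
        gbis = gbi_by_window(small_grid, 5.0, small_dataset.windows)
        assert len(gbis) == small_dataset.config.n_days
        rows_per_day = [g.matrix.shape[0] for g in gbis]
        assert all(r >= small_dataset.config.steps_per_window for r in rows_per_day)
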