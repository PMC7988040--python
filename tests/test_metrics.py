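"""Topology indexes against closed forms, brute-force oracles and networkx."""

import networkx as nx
import numpy as np
import pytest

from microgt import reference as ref
from microgt.metrics import (
    assortativity,
    betweenness,
    characteristic_path_length,
    degree_stats,
    detect_communities,
    global_efficiency,
    metrics_report,
    modularity,
)


def graph(edges, n=None):
    n = n if n is not None else max(max(e[:2]) for e in edges) + 1
    a = np.zeros((n, n))
    for e in edges:
        i, j = e[:2]
        w = e[2] if len(e) > 2 else 1.0
        a[i, j] = a[j, i] = w
    return a

P3 = graph([(0, 1), (1, 2)])
K3 = graph([(0, 1), (1, 2), (0, 2)])
K4 = graph([(i, j) for i in range(4) for j in range(i + 1, 4)])
TWO_TRIANGLES = graph(
    [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], n=6
)
STAR4 = graph([(0, 1), (0, 2), (0, 3)])
STAR5 = graph([(0, i) for i in range(1, 5)])
C4 = graph([(0, 1), (1, 2), (2, 3), (3, 0)])
TWO_EDGES = graph([(0, 1), (2, 3)], n=4)


def random_graph(rng, weighted):
    n = rng.integers(3, 8)
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.55:
                a[i, j] = a[j, i] = rng.uniform(0.1, 1.0) if weighted else 1.0
    return a


class TestClosedForms:
    def test_degrees(self):
        deg, mean = degree_stats(K4, weighted=False)
        assert deg.tolist() == [3, 3, 3, 3] and mean == 3
        deg, mean = degree_stats(P3, weighted=False)
        assert deg.tolist() == [1, 2, 1] and mean == pytest.approx(4 / 3)
        deg, mean = degree_stats(np.zeros((3, 3)), weighted=False)
        assert deg.tolist() == [0, 0, 0]

    def test_path_length(self):
        assert characteristic_path_length(K3, weighted=False)[0] == 1.0
        assert characteristic_path_length(P3, weighted=False)[0] == pytest.approx(4 / 3)
        L, n_disc = characteristic_path_length(TWO_EDGES, weighted=False)
        assert L == 1.0 and n_disc == 4

    def test_global_efficiency(self):
        assert global_efficiency(K4, weighted=False) == 1.0
        assert global_efficiency(P3, weighted=False) == pytest.approx(5 / 6)
        assert global_efficiency(np.zeros((4, 4)), weighted=False) == 0.0

    def test_complete_graphs_through_n8(self):
        for n in range(2, 9):
            kn = graph([(i, j) for i in range(n) for j in range(i + 1, n)], n=n)
            assert global_efficiency(kn, weighted=False) == 1.0
            assert characteristic_path_length(kn, weighted=False)[0] == 1.0

    def test_modularity_two_triangles(self):
        part = {i: i // 3 for i in range(6)}
        assert modularity(TWO_TRIANGLES, part, weighted=False) == pytest.approx(0.5)

    def test_modularity_single_community_is_zero(self):
        part = {i: 0 for i in range(4)}
        assert modularity(K4, part, weighted=False) == pytest.approx(0.0, abs=1e-12)

    def test_betweenness_p3_and_stars(self):
        bc, _ = betweenness(P3, weighted=False)
        assert bc.tolist() == [0.0, 1.0, 0.0]
        bc, _ = betweenness(STAR5, weighted=False)
        assert bc[0] == 6.0  # C(4,2) leaf pairs through the hub
        bc, _ = betweenness(K4, weighted=False)
        assert np.all(bc == 0.0)

    def test_assortativity_star_and_cycle(self):
        r, ok = assortativity(STAR4, weighted=False)
        assert ok and r == pytest.approx(-1.0)
        r, ok = assortativity(C4, weighted=False)
        assert not ok and np.isnan(r)


class TestOracles:
    @pytest.mark.parametrize("weighted", [False, True])
    def test_metrics_match_brute_force(self, weighted):
        rng = np.random.default_rng(17 + weighted)
        checked = 0
        for _ in range(50):
            a = random_graph(rng, weighted)
            if a.sum() == 0:
                continue
            deg, _ = degree_stats(a, weighted=weighted)
            np.testing.assert_allclose(deg, ref.brute_degrees(a, weighted), atol=1e-9)
            L, nd = characteristic_path_length(a, weighted=weighted)
            L0, nd0 = ref.brute_path_length(a, weighted)
            assert nd == nd0
            if np.isnan(L0):
                assert np.isnan(L)
            else:
                assert L == pytest.approx(L0, abs=1e-9)
            assert global_efficiency(a, weighted=weighted) == pytest.approx(
                ref.brute_global_efficiency(a, weighted), abs=1e-9
            )
            bc, _ = betweenness(a, weighted=weighted)
            np.testing.assert_allclose(bc, ref.brute_betweenness(a, weighted), atol=1e-9)
            part = detect_communities(a, seed=0, weighted=weighted)
            labels = np.array([part[i] for i in range(a.shape[0])])
            q = modularity(a, part, weighted=weighted)
            assert q == pytest.approx(ref.brute_modularity(a, labels), abs=1e-9)
            r, ok = assortativity(a, weighted=weighted)
            r0 = ref.brute_assortativity(a, weighted)
            if ok:
                assert r == pytest.approx(r0, abs=1e-9)
            else:
                assert np.isnan(r0)
            checked += 1
        assert checked >= 40

    def test_weighted_metrics_match_networkx(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = random_graph(rng, weighted=True)
            if a.sum() == 0:
                continue
            g = nx.from_numpy_array(a)
            for u, v, d in g.edges(data=True):
                d["dist"] = 1.0 / d["weight"]
            bc_nx = nx.betweenness_centrality(g, weight="dist", normalized=False)
            bc, _ = betweenness(a, weighted=True)
            np.testing.assert_allclose(bc, [bc_nx[i] for i in range(a.shape[0])],
                                       atol=1e-9)
            eff = global_efficiency(a, weighted=False)
            assert eff == pytest.approx(nx.global_efficiency(nx.from_numpy_array((a > 0) * 1.0)),
                                        abs=1e-9)

    def test_greedy_partition_close_to_exhaustive_optimum(self):
        rng = np.random.default_rng(11)
        ok = 0
        for _ in range(20):
            a = random_graph(rng, weighted=False)
            if a.sum() == 0:
                continue
            q_best, _ = ref.brute_best_partition(a)
            part = detect_communities(a, seed=0)
            q = modularity(a, part)
            assert q <= q_best + 1e-12
            ok += q >= q_best - 0.1
        assert ok >= 15  # greedy is near-optimal on small graphs


class TestDetection:
    def test_planted_two_module_graph(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 24
            labels = np.repeat([0, 1], n // 2)
            p = np.where(np.equal.outer(labels, labels), 0.7, 0.1)
            a = np.triu((rng.random((n, n)) < p) * 1.0, 1)
            a = a + a.T
            part = detect_communities(a, seed=seed)
            pred = [part[i] for i in range(n)]
            hits += adjusted_rand_score(labels, pred) > 0.9
        assert hits >= 18

    def test_deterministic_given_seed(self, rng):
        a = random_graph(np.random.default_rng(2), weighted=True)
        assert detect_communities(a, seed=3) == detect_communities(a, seed=3)

    def test_partition_missing_nodes_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            modularity(K4, {0: 0, 1: 0})


class TestProperties:
    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = random_graph(rng, weighted=False)
            deg, _ = degree_stats(a, weighted=False)
            assert deg.sum() == a.sum()  # adjacency already counts both directions

    def test_adding_edge_never_hurts(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = random_graph(rng, weighted=False)
            zeros = np.argwhere(np.triu(a == 0, 1))
            if not len(zeros):
                continue
            i, j = zeros[rng.integers(len(zeros))]
            b = a.copy()
            b[i, j] = b[j, i] = 1.0
            assert global_efficiency(b, weighted=False) >= global_efficiency(a, weighted=False)
            assert np.all(degree_stats(b, weighted=False)[0] >= degree_stats(a, weighted=False)[0])


def test_metrics_report_propagates_undefined_flags():
    rep = metrics_report(C4, seed=0, weighted=False)
    assert not rep.assortativity_defined
    assert rep.path_length_defined
    d = rep.to_dict()
    assert d["assortativity"] is None
    rep2 = metrics_report(np.zeros((3, 3)), seed=0, weighted=False)
    assert not rep2.path_length_defined
    assert rep2.mean_degree == 0.0


def test_metrics_report_weighted_consistency():
    rep = metrics_report(TWO_TRIANGLES, seed=1, weighted=True)
    assert rep.modularity_q == pytest.approx(0.5)
    assert len(rep.communities) == 6
    assert rep.n_disconnected_pairs == 9


def test_overlap_scores_match_direct_recomputation():
    """Move-gain formula equals recomputing Q with the node reassigned."""
    from microgt.metrics import community_overlap_scores

    rng = np.random.default_rng(21)
    for _ in range(10):
        a = random_graph(rng, weighted=True)
        if a.sum() == 0:
            continue
        part = detect_communities(a, seed=0)
        if len(set(part.values())) < 2:
            continue
        scores = community_overlap_scores(a, part)
        q0 = modularity(a, part)
        for i in range(a.shape[0]):
            best = -np.inf
            for c in set(part.values()):
                if c == part[i]:
                    continue
                moved = dict(part)
                moved[i] = c
                best = max(best, modularity(a, moved) - q0)
            assert scores[i] == pytest.approx(best, abs=1e-12)
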