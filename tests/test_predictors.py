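import itertools
import math

import networkx as nx
import numpy as np
import pytest

from commcouple.graph_core import ConnectivityMatrix, ParcelGeometry, validate_connectivity
from commcouple import predictors as pred


def _geometry(points):
    points = np.asarray(points, dtype=float)
    sphere = np.eye(3)[np.arange(len(points)) % 3]  # placeholder unit vectors
    # make them distinct
    sphere = np.array([[np.cos(a), np.sin(a), 0.0]
                       for a in np.linspace(0, np.pi, len(points), endpoint=False)])
    return ParcelGeometry(points, sphere, np.array(["s1"] * len(points)))


class TestFlowGraph:
    def test_zero_time_is_diagonal_strength(self, fixtures):
        sc, _ = fixtures["k3"]
        out = pred.flow_graph(sc, 0.0)
        s = sc.values.sum(axis=1)
        assert np.allclose(out, np.diag(s))

    def test_two_node_closed_form(self, fixtures):
        sc, _ = fixtures["two_node"]
        out = pred.flow_graph(sc, 1.0)
        assert out[0, 1] == pytest.approx((1 - np.exp(-2)) / 2, abs=1e-12)

    def test_marginals_conserved_and_symmetric(self, fixtures):
        sc, _ = fixtures["geometric10"]
        s = sc.values.sum(axis=1)
        for t in (1.0, 2.5, 5.0, 10.0):
            out = pred.flow_graph(sc, t)
            assert np.allclose(out.sum(axis=0), s, atol=1e-9)
            assert np.allclose(out, out.T, atol=1e-9)
            assert out.sum() == pytest.approx(s.sum())

    def test_long_time_stationary_limit(self):
        # complete graph: spectral gap of the walk is large, so t = 10 is
        # effectively stationary: A'(infinity)_ij = s_i s_j / sum(s)
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        sc = validate_connectivity(a)
        s = a.sum(axis=1)
        out = pred.flow_graph(sc, 10.0)
        assert np.allclose(out, np.outer(s, s) / s.sum(), atol=1e-3)


class TestCommunicability:
    def test_empty_graph_is_identity(self):
        sc = ConnectivityMatrix(np.zeros((4, 4)), kind="predictor")
        assert np.allclose(pred.communicability(sc, "binary"), np.eye(4))

    def test_two_node_sinh(self, fixtures):
        sc, _ = fixtures["two_node"]
        g = pred.communicability(sc, "binary")
        assert g[0, 1] == pytest.approx(np.sinh(1), abs=1e-12)
        assert g[0, 0] == pytest.approx(np.cosh(1), abs=1e-12)

    def test_matches_truncated_series(self, fixtures):
        sc, _ = fixtures["geometric10"]
        a = (sc.values > 0).astype(float)
        series = sum(np.linalg.matrix_power(a, p) / math.factorial(p)
                     for p in range(31))
        assert np.allclose(pred.communicability(sc, "binary"), series, atol=1e-8)


class TestMatchingIndex:
    def test_star_leaves_fully_match(self, fixtures):
        sc, _ = fixtures["star5"]
        m = pred.matching_index(sc, "binary")
        for i, j in itertools.combinations(range(1, 5), 2):
            assert m[i, j] == pytest.approx(1.0)

    def test_disjoint_neighbourhoods_give_zero(self):
        # path of 4: ends share no neighbours
        a = np.diag([1.0, 1, 1], 1)
        sc = validate_connectivity(a + a.T)
        m = pred.matching_index(sc, "binary")
        assert m[0, 3] == 0.0

    def test_weighted_equals_binary_on_binary_graph(self, fixtures):
        sc, _ = fixtures["geometric10"]
        binary = validate_connectivity((sc.values > 0).astype(float))
        assert np.allclose(pred.matching_index(binary, "weighted"),
                           pred.matching_index(binary, "binary"))

    def test_values_in_unit_interval(self, subject):
        for variant in ("binary", "weighted"):
            m = pred.matching_index(subject["sc"], variant)
            assert np.all(m >= 0) and np.all(m <= 1 + 1e-12)


class TestShortestPaths:
    def test_binary_path_graph_hop_counts(self):
        a = np.diag(np.ones(4), 1)
        sc = validate_connectivity(a + a.T)
        d = pred.shortest_path_length(sc, "binary")
        assert d[0, 4] == 4

    def test_weighted_triangle_reroutes_through_strong_edges(self, fixtures):
        sc, _ = fixtures["weighted_triangle"]
        # gamma = 1: direct cost 1/0.1 = 10, detour 1 + 1 = 2
        assert pred.shortest_path_length(sc, 1.0)[0, 2] == pytest.approx(2.0)
        # gamma = 0.125: direct 0.1^-0.125 ~ 1.33 beats detour 2
        assert pred.shortest_path_length(sc, 0.125)[0, 2] == pytest.approx(0.1 ** -0.125)

    def test_raising_a_weight_never_lengthens_paths(self, subject, rng):
        sc = subject["sc"]
        base = pred.shortest_path_length(sc, 1.0)
        for _ in range(5):
            edges = np.argwhere(np.triu(sc.values) > 0)
            i, j = edges[rng.integers(len(edges))]
            bumped = sc.values.copy()
            bumped[i, j] = bumped[j, i] = bumped[i, j] * 3.0
            d = pred.shortest_path_length(validate_connectivity(bumped), 1.0)
            assert np.all(d <= base + 1e-12)


class TestPathTransitivity:
    def test_complete_graph_reduces_to_matching(self):
        a = np.ones((4, 4)) - np.eye(4)
        sc = validate_connectivity(a)
        m = pred.matching_index(sc, "binary")
        pt = pred.path_transitivity(sc, "binary")
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(pt[off], m[off])

    def test_path_graph_endpoints_brute_force(self):
        a = np.diag(np.ones(4), 1)
        sc = validate_connectivity(a + a.T)
        m = pred.matching_index(sc, "binary")
        nodes = [0, 1, 2, 3, 4]  # the unique shortest path
        expected = np.mean([m[i, j] for i, j in itertools.combinations(nodes, 2)])
        pt = pred.path_transitivity(sc, "binary")
        assert pt[0, 4] == pytest.approx(expected)

    def test_zero_when_path_nodes_share_no_neighbours(self):
        # middle pair of a 4-path: direct edge, external neighbourhoods disjoint
        a = np.diag(np.ones(3), 1)
        sc = validate_connectivity(a + a.T)
        pt = pred.path_transitivity(sc, "binary")
        assert pt[1, 2] == 0.0


class TestCosineSimilarity:
    def test_identical_external_profiles(self, fixtures):
        sc, _ = fixtures["star5"]
        s = pred.cosine_similarity(sc, "binary")
        assert s[1, 2] == pytest.approx(1.0)

    def test_orthogonal_profiles(self):
        a = np.diag([1.0, 1, 1], 1)
        sc = validate_connectivity(a + a.T)
        s = pred.cosine_similarity(sc, "binary")
        assert s[0, 3] == 0.0

    def test_hand_computed_dot_product(self):
        # rows 0 and 1 reduce to [1, 2] and [2, 1] after deleting the pair
        a = np.zeros((4, 4))
        a[0, 2], a[0, 3] = 1.0, 2.0
        a[1, 2], a[1, 3] = 2.0, 1.0
        a[2, 3] = 0.5  # keep the graph connected
        a[0, 1] = 3.0  # deleted from both rows
        sc = validate_connectivity(a + a.T)
        s = pred.cosine_similarity(sc, "weighted")
        assert s[0, 1] == pytest.approx(0.8)


class TestSearchInformation:
    def test_three_node_path_costs_one_bit(self, fixtures):
        sc, _ = fixtures["path3"]
        si = pred.search_information(sc, "binary")
        assert si[0, 2] == pytest.approx(1.0)

    def test_triangle_one_bit(self, fixtures):
        sc, _ = fixtures["k3"]
        si = pred.search_information(sc, "binary")
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(si[off], 1.0)

    def test_matches_enumerated_path_probability(self, fixtures):
        """Independent oracle: networkx shortest paths on unique-path pairs."""
        sc, _ = fixtures["geometric10"]
        a = sc.values
        gamma = 1.0
        g = nx.Graph()
        for i, j in zip(*np.nonzero(np.triu(a))):
            g.add_edge(int(i), int(j), cost=float(a[i, j] ** -gamma))
        strength = a.sum(axis=1)
        si = pred.search_information(sc, gamma)
        n = a.shape[0]
        raw = np.zeros((n, n))
        unique = np.ones((n, n), dtype=bool)
        for s in range(n):
            for t in range(n):
                if s == t:
                    continue
                paths = list(nx.all_shortest_paths(g, s, t, weight="cost"))
                if len(paths) > 1:
                    unique[s, t] = unique[t, s] = False
                    continue
                logp = sum(np.log2(a[u, v] / strength[u])
                           for u, v in zip(paths[0], paths[0][1:]))
                raw[s, t] = -logp
        sym = (raw + raw.T) / 2
        both = unique & unique.T & ~np.eye(n, dtype=bool)
        assert both.sum() > 20
        assert np.allclose(si[both], sym[both], atol=1e-10)


class TestMeanFirstPassageTime:
    def test_two_node_single_step(self, fixtures):
        sc, _ = fixtures["two_node"]
        raw = pred.mean_first_passage_time(sc, "binary", z_score=False)
        assert raw[0, 1] == pytest.approx(1.0)

    def test_cycle_closed_form(self, fixtures):
        # on an N-cycle, MFPT at hop distance k is k (N - k)
        sc, _ = fixtures["cycle4"]
        raw = pred.mean_first_passage_time(sc, "binary", z_score=False)
        assert raw[0, 1] == pytest.approx(3.0)
        assert raw[0, 2] == pytest.approx(4.0)

    def test_z_scored_columns_standardised(self, fixtures):
        sc, _ = fixtures["geometric10"]
        raw = pred.mean_first_passage_time(sc, "weighted", z_score=False)
        n = raw.shape[0]
        off = ~np.eye(n, dtype=bool)
        for j in range(n):
            col = raw[off[:, j], j]
            z = (col - col.mean()) / col.std(ddof=1)
            assert abs(z.mean()) < 1e-10
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_oracle(self, fixtures):
        """Raw MFPT agrees with a 100k-walk simulation within 3 SE."""
        sc, _ = fixtures["star5"]
        a = sc.values
        raw = pred.mean_first_passage_time(sc, "binary", z_score=False)
        rng = np.random.default_rng(42)
        n, n_walk = a.shape[0], 100_000
        p = a / a.sum(axis=1, keepdims=True)
        cum = np.cumsum(p, axis=1)
        for i, j in [(1, 0), (0, 1), (1, 2)]:
            pos = np.full(n_walk, i)
            steps = np.zeros(n_walk)
            alive = np.ones(n_walk, dtype=bool)
            for _ in range(10_000):
                if not alive.any():
                    break
                u = rng.random(alive.sum())
                pos[alive] = np.argmax(u[:, None] < cum[pos[alive]], axis=1)
                steps[alive] += 1
                alive &= pos != j
            se = steps.std() / np.sqrt(n_walk)
            assert abs(steps.mean() - raw[i, j]) < 3 * se + 1e-9


class TestNavigation:
    def test_complete_graph_single_hops(self):
        n = 5
        pts = np.column_stack([np.cos(np.linspace(0, 2 * np.pi, n, endpoint=False)),
                               np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False)),
                               np.zeros(n)]) * 50
        geo = _geometry(pts)
        sc = validate_connectivity(np.ones((n, n)) - np.eye(n))
        num, ms = pred.navigation(sc, geo)
        euc = pred.euclidean_matrix(geo)
        off = ~np.eye(n, dtype=bool)
        assert np.all(num[off] == 1)
        assert np.allclose(ms[off], euc[off])

    def test_collinear_chain_walks_straight(self):
        n = 6
        pts = np.column_stack([np.arange(n) * 10.0, np.zeros(n), np.zeros(n)])
        geo = _geometry(pts)
        a = np.diag(np.ones(n - 1), 1)
        sc = validate_connectivity(a + a.T)
        num, _ = pred.navigation(sc, geo)
        for i in range(n):
            for j in range(n):
                if i != j:
                    assert num[i, j] == abs(i - j)

    def test_dead_end_yields_infinity(self):
        # node 1 is nearest to target 3 from node 0, but from node 1 the only
        # moves revisit or move away, so greedy routing 0 -> 3 fails
        pts = np.array([[0.0, 0, 0], [10.0, 3, 0], [9.0, -8, 0], [20.0, 0, 0]])
        geo = _geometry(pts)
        a = np.zeros((4, 4))
        a[0, 1] = a[0, 2] = 1.0
        a[2, 3] = 1.0
        sc = validate_connectivity(a + a.T)
        num, ms = pred.navigation(sc, geo)
        assert np.isinf(num[0, 3]) and np.isinf(ms[0, 3])

    def test_matches_step_by_step_oracle(self, fixtures):
        """Independent simulation of the greedy rule, exact incl. failures."""
        sc, geo = fixtures["geometric10"]
        a = sc.values
        euc = pred.euclidean_matrix(geo)
        n = a.shape[0]
        raw_num = np.zeros((n, n))
        raw_ms = np.zeros((n, n))
        for s in range(n):
            for t in range(n):
                if s == t:
                    continue
                cur, visited, hops, length = s, {s}, 0, 0.0
                while cur != t:
                    nbrs = np.where(a[cur] > 0)[0]
                    nxt = nbrs[np.argmin(euc[nbrs, t])]
                    hops += 1
                    length += euc[cur, nxt]
                    cur = int(nxt)
                    if cur in visited or hops > n:
                        hops, length = np.inf, np.inf
                        break
                    visited.add(cur)
                raw_num[s, t] = hops
                raw_ms[s, t] = length
        num, ms = pred.navigation(sc, geo)
        assert np.array_equal(num, (raw_num + raw_num.T) / 2)
        assert np.array_equal(ms, (raw_ms + raw_ms.T) / 2)


class TestBattery:
    def test_deterministic(self, fixtures):
        sc, geo = fixtures["geometric10"]
        s1 = pred.build_battery(sc, geo)
        s2 = pred.build_battery(sc, geo)
        for a, b in zip(s1.matrices, s2.matrices):
            assert np.array_equal(a, b)

    def test_matrix_invariants(self, subject):
        stack = subject["stack"]
        for lbl, m in zip(stack.labels, stack.matrices):
            assert np.allclose(m, m.T, equal_nan=True), lbl
            assert np.allclose(np.diag(m), 0), lbl
            if not lbl.startswith("nav"):
                assert np.all(np.isfinite(m)), lbl
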