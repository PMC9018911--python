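import numpy as np
import pytest

from commcouple.graph_core import ConnectivityMatrix
from commcouple import regression as reg


class TestSimpleFit:
    def test_exact_line(self):
        r2, b0, b1 = reg.simple_fit(np.arange(10.0), np.arange(10.0) * 2 + 1)
        assert r2 == pytest.approx(1.0)

    def test_constant_predictor_raises(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            reg.simple_fit(rng.normal(size=20), np.ones(20))

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.normal(size=30)
        x = rng.normal(size=30)
        # independent oracle: solve the normal equations directly
        xd = np.column_stack([np.ones(30), x])
        beta = np.linalg.solve(xd.T @ xd, xd.T @ y)
        resid = y - xd @ beta
        expected = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        r2, b0, b1 = reg.simple_fit(y, x)
        assert r2 == pytest.approx(expected, abs=1e-12)
        assert (b0, b1) == pytest.approx(tuple(beta), abs=1e-10)

    def test_non_finite_predictor_entries_are_dropped(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + 1
        x_inf = x.copy()
        x_inf[:5] = np.inf
        r2, *_ = reg.simple_fit(y, x_inf)
        assert r2 == pytest.approx(1.0)

    def test_too_few_samples_gives_missing(self, rng):
        r2, *_ = reg.simple_fit(rng.normal(size=5), rng.normal(size=5))
        assert np.isnan(r2)


class TestAdjustedR2:
    def test_perfect_fit_unchanged(self):
        assert reg.adjusted_r2(1.0, 399, 2) == pytest.approx(1.0)

    def test_printed_formula_value(self):
        assert reg.adjusted_r2(0.5, 399, 2) == pytest.approx(1 - 0.5 * 398 / 396)

    def test_never_exceeds_raw(self, rng):
        for _ in range(20):
            r2 = rng.uniform(0, 1)
            n = int(rng.integers(10, 500))
            assert reg.adjusted_r2(r2, n, 2) <= r2 + 1e-12

    def test_insufficient_samples_raise(self):
        with pytest.raises(ValueError):
            reg.adjusted_r2(0.5, 3, 2)


class TestGlobalCoupling:
    def test_planted_identity(self, subject):
        stack = subject["stack"]
        k = stack.labels.index("comm-wei")
        fc = ConnectivityMatrix(0.3 * stack.matrices[k] + 0.1, kind="functional")
        r2, _ = reg.global_coupling(fc, stack)
        assert r2[k] == pytest.approx(1.0)

    def test_noise_fc_explains_nothing(self, subject, rng):
        n = subject["sc"].n_nodes
        noise = rng.normal(size=(n, n))
        fc = ConnectivityMatrix((noise + noise.T) / 2, kind="functional")
        r2, _ = reg.global_coupling(fc, subject["stack"])
        assert np.nanmax(r2) < 0.05

    def test_relabeling_invariance(self, subject, rng):
        stack = subject["stack"]
        fc = subject["fc"]
        r2, _ = reg.global_coupling(fc, stack)
        perm = rng.permutation(fc.n_nodes)
        fc_p = ConnectivityMatrix(fc.values[np.ix_(perm, perm)], kind="functional")
        stack_p = type(stack)(
            matrices=[m[np.ix_(perm, perm)] for m in stack.matrices],
            labels=stack.labels, class_of=stack.class_of)
        r2_p, _ = reg.global_coupling(fc_p, stack_p)
        assert np.allclose(r2, r2_p, equal_nan=True)


class TestHopDecomposition:
    def test_strata_partition_all_pairs(self, subject):
        hops, r2 = reg.hop_decomposition(subject["fc"], subject["stack"], subject["sc"])
        from commcouple.predictors import hop_distance
        n = subject["sc"].n_nodes
        iu = np.triu_indices(n, 1)
        h = hop_distance(subject["sc"])[iu]
        assert sum((h == s).sum() for s in hops) == len(h)

    def test_direct_stratum_dominates_for_edge_built_fc(self, subject, rng):
        # FC follows the predictor only on directly connected pairs
        sc = subject["sc"]
        n = sc.n_nodes
        x = rng.normal(size=(n, n))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0.0)
        edge = sc.values > 0
        fcv = np.where(edge, x, rng.normal(size=(n, n)))
        fcv = (fcv + fcv.T) / 2
        np.fill_diagonal(fcv, 0.0)
        fc = ConnectivityMatrix(fcv, kind="functional")
        stack = type(subject["stack"])(matrices=[x], labels=["x"],
                                       class_of={"x": "x"})
        hops, r2 = reg.hop_decomposition(fc, stack, sc)
        assert r2[0, 0] > 0.99
        assert np.all(r2[1:, 0] < 0.2)


class TestRegionalCoupling:
    def test_affine_fc_row_gives_unit_r2(self, subject):
        stack = subject["stack"]
        n = subject["sc"].n_nodes
        k = stack.labels.index("euc")
        fcv = 0.4 * stack.matrices[k] + 0.1
        np.fill_diagonal(fcv, 0.0)
        fc = ConnectivityMatrix(fcv, kind="functional")
        r2, n_used = reg.regional_coupling(fc, stack)
        assert r2.shape == (n, len(stack))
        assert np.allclose(r2[:, k], 1.0)
        assert np.all(n_used <= n - 1)

    def test_affine_rescaling_invariance(self, subject):
        stack = subject["stack"]
        r2, _ = reg.regional_coupling(subject["fc"], stack)
        scaled = type(stack)(matrices=[5 * m + 3 for m in stack.matrices],
                             labels=stack.labels, class_of=stack.class_of)
        r2_s, _ = reg.regional_coupling(subject["fc"], scaled)
        assert np.allclose(r2, r2_s, equal_nan=True, atol=1e-8)


class TestBestPredictor:
    def test_ties_break_to_earlier_label(self):
        r2 = np.array([[0.5, 0.5, 0.1]])
        lbl, val = reg.best_predictor(r2, ["a", "b", "c"])
        assert lbl[0] == "a" and val[0] == 0.5

    def test_unique_maximum(self):
        r2 = np.array([[0.1, 0.9, 0.3], [0.4, 0.2, 0.6]])
        lbl, _ = reg.best_predictor(r2, ["a", "b", "c"])
        assert list(lbl) == ["b", "c"]


class TestGreedyPair:
    def test_planted_pair_recovered_on_weakly_correlated_design(self, rng):
        """Rows built as x_j + x_k with weak mutual correlation, 10% noise."""
        rows = rng.normal(size=(12, 120))
        j, k = 3, 8
        hits = 0
        for _ in range(50):
            y = rows[j] + rows[k] + 0.1 * np.sqrt(2) * rng.normal(size=120)
            res = reg.greedy_pair_fit(y, rows)
            hits += {res["best"], res["second"]} == {j, k}
        assert hits >= 45

    def test_pair_r2_at_least_single(self, subject, rng):
        stack = subject["stack"]
        rows = np.array(stack.matrices)[:, 3, :]
        y = rng.normal(size=rows.shape[1])
        res = reg.greedy_pair_fit(y, rows)
        assert res["r2_pair"] >= res["r2_single"] - 1e-12
        assert res["second"] != res["best"]


class TestPairCounts:
    def test_single_selection(self):
        pc = reg.pair_counts([(2, 5)], 10)
        assert pc.counts[2, 5] == pc.counts[5, 2] == 1
        assert pc.counts.sum() == 2
        assert pc.total_selections == 1

    def test_total_conserved(self, rng):
        sels = [tuple(sorted(rng.choice(40, 2, replace=False))) for _ in range(100)]
        pc = reg.pair_counts(sels, 40)
        assert pc.total_selections == 100
        assert np.all(np.diag(pc.counts) == 0)


class TestFullAndPcaModels:
    def test_nested_r2_ordering(self, subject, rng):
        stack = subject["stack"]
        rows = np.array(stack.matrices)[:, 7, :]
        y = rng.normal(size=rows.shape[1])
        pair = reg.greedy_pair_fit(y, rows)
        full, kept = reg.full_model_fit(y, rows)
        assert full >= pair["r2_pair"] - 1e-10

    def test_duplicated_predictors_leave_r2_unchanged(self, rng):
        x = rng.normal(size=(5, 50))
        y = x[0] + 0.5 * rng.normal(size=50)
        r2a, _ = reg.full_model_fit(y, x)
        r2b, _ = reg.full_model_fit(y, np.vstack([x, x[0]]))
        assert r2a == pytest.approx(r2b, abs=1e-10)

    def test_pca_full_rank_equals_full_model(self, rng):
        x = rng.normal(size=(6, 80))
        y = x[1] - x[3] + 0.2 * rng.normal(size=80)
        full, kept = reg.full_model_fit(y, x)
        assert reg.pca_predictor_fit(y, x, k=len(kept)) == pytest.approx(full, abs=1e-10)

    def test_pca_needs_enough_predictors(self, rng):
        x = rng.normal(size=(3, 40))
        with pytest.raises(ValueError):
            reg.pca_predictor_fit(rng.normal(size=40), x, k=10)


class TestScDirectFit:
    def test_exact_on_edges(self, subject):
        sc = subject["sc"]
        fc = ConnectivityMatrix(0.7 * sc.values + 0.05, kind="functional")
        r2 = reg.sc_direct_fit(fc, sc)
        ok = np.isfinite(r2)
        assert ok.sum() > 0
        assert np.allclose(r2[ok], 1.0)

    def test_sparse_region_missing(self, subject):
        sc = subject["sc"]
        sparse = sc.values.copy()
        sparse[0, :] = sparse[:, 0] = 0.0
        keep = np.argmax(sparse[1] > 0)  # keep one edge so shapes survive
        sparse[0, 1] = sparse[1, 0] = 1.0
        thin = ConnectivityMatrix(sparse)
        r2 = reg.sc_direct_fit(subject["fc"], thin)
        assert np.isnan(r2[0])


class TestOptimalFrequency:
    def test_single_subject_one_hot(self):
        best = np.array([["a", "b"]], dtype=object)
        h = reg.optimal_frequency(best, ["a", "b", "c"])
        assert np.array_equal(h, [[1, 0, 0], [0, 1, 0]])

    def test_rows_sum_to_one(self, rng):
        labels = ["a", "b", "c", "d"]
        best = rng.choice(labels, size=(7, 12)).astype(object)
        h = reg.optimal_frequency(best, labels)
        assert np.allclose(h.sum(axis=1), 1.0, atol=1e-12)


class TestPredictorEmbedding:
    def test_identical_predictors_coincide(self, subject, rng):
        r2 = rng.uniform(0, 0.4, size=(60, 10))
        r2[:, 4] = r2[:, 2]
        coords, thr = reg.predictor_embedding(r2, k=3)
        assert coords.shape == (10, 2)
        assert np.allclose(coords[2], coords[4], atol=1e-8)

    def test_constant_column_rejected(self, rng):
        r2 = rng.uniform(size=(30, 6))
        r2[:, 0] = 0.2
        with pytest.raises(ValueError):
            reg.predictor_embedding(r2)
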