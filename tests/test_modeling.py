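import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from mpbreak.descriptors import FingerprintKind, FingerprintMatrix
from mpbreak.modeling import (
    BenchmarkResult,
    HyperSearchSpec,
    compare_models,
    default_registry,
    fit_bias_correction,
    load_bundle,
    nested_cv_benchmark,
    optimize_final,
    outer_fold_assignments,
    predict_bundle,
    r2,
    save_bundle,
    select_best,
    train_bundle,
    y_scramble,
)

FAST_REGRESSORS = ["MLR", "RF", "KNN"]


def _toy_matrix(n=60, n_bits=12, seed=0, noise=0.1):
    """Binary features with a planted linear signal."""
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n, n_bits)).astype(np.uint8)
    ids = [f"s{i}" for i in range(n)]
    m = FingerprintMatrix(FingerprintKind.MACCS, ids,
                          bits, [f"maccs_{i+1}" for i in range(n_bits)])
    y = pd.Series(
        0.8 * bits[:, 0] - 0.6 * bits[:, 1] + rng.normal(0, noise, n), index=ids
    )
    return m, y


class TestRegistry:
    def test_twelve_families(self):
        reg = default_registry()
        assert len(reg) == 12
        assert {"MLR", "Ridge", "KR", "SGD", "LSVR", "RF", "GBR", "AB", "DT",
                "MLP", "SVR", "KNN"} == set(reg)

    def test_uniform_contract(self):
        for spec in default_registry().values():
            est = spec.factory(0)
            assert hasattr(est, "fit") and hasattr(est, "predict")


class TestNestedCV:
    def test_constant_y_never_positive_r2(self):
        m, _ = _toy_matrix()
        y = pd.Series(np.full(len(m.substance_ids), -1.0), index=m.substance_ids)
        results = nested_cv_benchmark(m, y, regressors=FAST_REGRESSORS, seed=0)
        for r in results:
            assert all(score <= 0 for score in r.fold_r2)

    def test_planted_signal_recovered(self):
        m, y = _toy_matrix(n=120, noise=0.1)
        results = nested_cv_benchmark(m, y, regressors=["RF"], seed=1)
        assert results[0].mean_r2 > 0.5

    def test_folds_partition_and_are_shared(self):
        m, y = _toy_matrix()
        assignment = outer_fold_assignments(m.substance_ids, seed=4, n_outer=5)
        folds = pd.Series(assignment)
        assert set(folds) == set(range(5))
        for f in range(5):
            test = set(folds.index[folds == f])
            train = set(folds.index[folds != f])
            assert test.isdisjoint(train)
            assert test | train == set(m.substance_ids)
        # identical on recomputation (shared across regressor-descriptor pairs)
        assert assignment == outer_fold_assignments(m.substance_ids, seed=4, n_outer=5)

    def test_determinism_bit_identical(self):
        m, y = _toy_matrix()
        a = nested_cv_benchmark(m, y, regressors=["RF"], seed=7)[0]
        b = nested_cv_benchmark(m, y, regressors=["RF"], seed=7)[0]
        assert a.fold_r2 == b.fold_r2
        assert a.fold_rmse == b.fold_rmse
        assert a.fold_params == b.fold_params

    def test_results_sorted_by_mean_r2(self):
        m, y = _toy_matrix()
        results = nested_cv_benchmark(m, y, regressors=FAST_REGRESSORS, seed=0)
        scores = [r.mean_r2 for r in results]
        assert scores == sorted(scores, reverse=True)

    def test_non_finite_targets_hard_error(self):
        m, y = _toy_matrix()
        y.iloc[3] = np.nan
        with pytest.raises(ValueError, match=y.index[3]):
            nested_cv_benchmark(m, y, regressors=["MLR"])

    def test_r2_zero_variance_convention(self):
        assert r2([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert r2([1.0, 2.0], [1.0, 2.0]) == 1.0


class TestYScramble:
    def test_null_near_zero_and_signal_above(self):
        m, y = _toy_matrix(n=100, noise=0.1)
        out = y_scramble(m, y, n_repeats=5, seed=0, regressor="RF")
        assert np.mean(out["null_scores"]) <= 0.05
        assert out["unscrambled_score"] > np.quantile(out["null_scores"], 0.95)
        assert out["percentile"] == 1.0

    def test_deterministic(self):
        m, y = _toy_matrix(n=50)
        a = y_scramble(m, y, n_repeats=3, seed=5)
        b = y_scramble(m, y, n_repeats=3, seed=5)
        assert np.array_equal(a["null_scores"], b["null_scores"])

    def test_requires_repeats(self):
        m, y = _toy_matrix(n=30)
        with pytest.raises(ValueError):
            y_scramble(m, y, n_repeats=0)


class TestSelectBest:
    def test_fewer_trees_win_ties(self):
        a = {"n_estimators": 500, "max_depth": 10, "min_samples_split": 2}
        b = {"n_estimators": 100, "max_depth": 10, "min_samples_split": 2}
        assert select_best([(a, 0.5), (b, 0.5)]) == b

    def test_larger_min_split_wins_ties(self):
        a = {"n_estimators": 100, "max_depth": 10, "min_samples_split": 2}
        b = {"n_estimators": 100, "max_depth": 10, "min_samples_split": 10}
        assert select_best([(a, 0.5), (b, 0.5)]) == b

    def test_none_depth_is_most_complex(self):
        a = {"n_estimators": 100, "max_depth": None, "min_samples_split": 2}
        b = {"n_estimators": 100, "max_depth": 5, "min_samples_split": 2}
        assert select_best([(a, 0.5), (b, 0.5)]) == b

    def test_better_score_beats_simplicity(self):
        a = {"n_estimators": 500, "max_depth": None, "min_samples_split": 2}
        b = {"n_estimators": 100, "max_depth": 5, "min_samples_split": 10}
        assert select_best([(a, 0.9), (b, 0.5)]) == a

    def test_single_candidate_returned(self):
        only = {"n_estimators": 10, "max_depth": 3, "min_samples_split": 2}
        assert select_best([(only, -1.0)]) == only

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


def test_optimize_final_runs_and_is_deterministic():
    m, y = _toy_matrix(n=60)
    spec = HyperSearchSpec(n_estimators=(10, 25), max_depth=(3, None),
                           min_samples_split=(2, 5), max_features=("sqrt",), n_random=4)
    a = optimize_final(m, y, spec, seed=2)
    b = optimize_final(m, y, spec, seed=2)
    assert a == b
    assert a["n_estimators"] in (10, 25)


def test_empty_search_space_rejected():
    with pytest.raises(ValueError):
        HyperSearchSpec(n_estimators=())


class TestBiasCorrection:
    def test_perfect_predictor_identity(self):
        y = np.array([-2.0, -1.0, 0.0, 1.0])
        slope, intercept = fit_bias_correction(y, y)
        assert slope == pytest.approx(1.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_range_compressed_predictor(self):
        y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        slope, intercept = fit_bias_correction(0.5 * y, y)
        assert slope == pytest.approx(2.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_predictions_warn_identity_slope(self):
        y = np.array([0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="constant raw predictions"):
            slope, intercept = fit_bias_correction(np.full(3, 5.0), y)
        assert slope == 1.0
        assert intercept == pytest.approx(np.mean(y) - 5.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_bias_correction([1.0, 2.0], [1.0, 2.0])  # < 3 points
        with pytest.raises(ValueError):
            fit_bias_correction([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])

    def test_simulated_compression_recovered(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 200)
        raw = 0.6 * y + rng.normal(0, 0.05, 200)  # compressed extremes
        slope, intercept = fit_bias_correction(raw, y)
        adjusted = slope * raw + intercept
        raw_slope = np.polyfit(y, raw, 1)[0]
        adj_slope = np.polyfit(y, adjusted, 1)[0]
        assert abs(adj_slope - 1.0) < abs(raw_slope - 1.0)


class TestBundle:
    def test_memorization_of_training_points(self):
        m, y = _toy_matrix(n=40, noise=0.0)
        bundle = train_bundle(m, y, params={"n_estimators": 200, "max_depth": None}, seed=0)
        preds = predict_bundle(bundle, m)
        assert np.allclose(preds["adjusted_logB"], y.loc[preds["substance_id"]], atol=0.15)
        assert (preds["similarity_nearest"] == 1.0).all()  # queries are training points

    def test_single_tree_bundle_tree_sd_zero(self):
        m, y = _toy_matrix(n=30)
        bundle = train_bundle(m, y, params={"n_estimators": 1}, seed=0)
        preds = predict_bundle(bundle, m)
        assert (preds["tree_sd"] == 0.0).all()
        assert (preds["confidence"] == 1.0).all()

    def test_bias_monotone_affine_preserves_ranking(self):
        m, y = _toy_matrix(n=50)
        bundle = train_bundle(m, y, params={"n_estimators": 30}, seed=0)
        assert bundle.bias_slope > 0
        preds = predict_bundle(bundle, m)
        raw_rank = preds["raw_logB"].rank()
        adj_rank = preds["adjusted_logB"].rank()
        assert (raw_rank == adj_rank).all()

    def test_descriptor_kind_mismatch_rejected(self):
        m, y = _toy_matrix(n=30)
        bundle = train_bundle(m, y, params={"n_estimators": 5}, seed=0)
        other = FingerprintMatrix(FingerprintKind.EPFP, m.substance_ids, m.bits,
                                  m.bit_names)
        with pytest.raises(ValueError, match="descriptor kind"):
            predict_bundle(bundle, other)

    def test_missing_features_rejected(self):
        m, y = _toy_matrix(n=30, n_bits=8)
        bundle = train_bundle(m, y, params={"n_estimators": 5}, seed=0)
        narrow = FingerprintMatrix(FingerprintKind.MACCS, m.substance_ids,
                                   m.bits[:, :4], m.bit_names[:4])
        with pytest.raises(ValueError, match="lacks bundle features"):
            predict_bundle(bundle, narrow)

    def test_save_load_roundtrip(self, tmp_path):
        m, y = _toy_matrix(n=30)
        bundle = train_bundle(m, y, params={"n_estimators": 10}, seed=0)
        path = tmp_path / "bundle.joblib"
        save_bundle(bundle, str(path))
        assert path.exists() and path.with_suffix(".joblib.json").exists()
        loaded = load_bundle(str(path))
        a = predict_bundle(bundle, m)
        b = predict_bundle(loaded, m)
        pd.testing.assert_frame_equal(a, b)

    def test_prediction_throughput(self):
        """Batch of 1000 rows predicts in well under a minute."""
        import time

        m, y = _toy_matrix(n=200, n_bits=166)
        bundle = train_bundle(m, y, params={"n_estimators": 100}, seed=0)
        rng = np.random.default_rng(1)
        big = FingerprintMatrix(
            FingerprintKind.MACCS,
            [f"q{i}" for i in range(1000)],
            rng.integers(0, 2, size=(1000, 166)).astype(np.uint8),
            m.bit_names,
        )
        start = time.monotonic()
        preds = predict_bundle(bundle, big)
        assert time.monotonic() - start < 60
        assert len(preds) == 1000


class TestCompareModels:
    def _result(self, name, scores, seed=0):
        return BenchmarkResult(name, "MACCS", scores, [0.5] * len(scores),
                               [{}] * len(scores), seed, len(scores))

    def test_self_comparison_p_one(self):
        r = self._result("A", [0.1, 0.2, 0.3, 0.4, 0.5])
        table = compare_models([r])
        assert table.loc[0, "p_value"] == 1.0
        assert table.loc[0, "median_diff"] == 0.0

    def test_dominant_regressor_exact_min_p(self):
        # one-sided exact signed-rank with n=5 and all positive diffs: p = 1/32
        a = self._result("A", [0.5, 0.6, 0.55, 0.7, 0.65])
        b = self._result("B", [0.1, 0.2, 0.15, 0.3, 0.25])
        table = compare_models([a, b]).set_index(["regressor_a", "regressor_b"])
        assert table.loc[("A", "B"), "p_value"] == pytest.approx(1 / 32)

    def test_effect_antisymmetric(self):
        a = self._result("A", [0.5, 0.6, 0.55, 0.7, 0.65])
        b = self._result("B", [0.1, 0.7, 0.15, 0.3, 0.25])
        table = compare_models([a, b]).set_index(["regressor_a", "regressor_b"])
        assert table.loc[("A", "B"), "median_diff"] == -table.loc[("B", "A"), "median_diff"]

    def test_mismatched_folds_rejected(self):
        a = self._result("A", [0.5] * 5, seed=0)
        b = self._result("B", [0.1] * 5, seed=1)
        with pytest.raises(ValueError, match="different outer folds"):
            compare_models([a, b])
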