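"""Cirrhosis map (logarithmic R15 relation), features, metrics, cutoffs."""

import numpy as np
import pytest

from icgpbpk.classify import (
    MODEL_NAMES,
    CirrhosisMapCoefficients,
    PatientRecord,
    REFERENCE_COEFFICIENTS,
    build_features,
    confusion_metrics,
    cutoff_scan,
    estimate_fcirrhosis,
    evaluate,
    fit_map_coefficients,
    predict_postop_r15,
)
from icgpbpk.nca import PKResults
from icgpbpk.scenarios import ScanTable


def synthetic_scan(a=0.312, b=1.693, c=0.861, f_grid=None):
    """ScanTable whose R15 column follows the logarithmic map exactly."""
    if f_grid is None:
        f_grid = np.round(np.arange(0.05, 0.91, 0.05), 10)
    f_grid = np.asarray(f_grid)
    r15 = np.exp((f_grid - c) / a) / b
    results = [
        PKResults(kel=1.0, pdr=100.0, t_half=np.log(2), auc_inf=1.0, vd=1.0,
                  cl=1.0, r15=float(r), r20=float(r) * 0.8, c_max=1.0, c0=1.0,
                  dose_mg=37.5, window=(5.0, 15.0), r_squared=1.0)
        for r in r15
    ]
    return ScanTable("f_cirrhosis", f_grid, results, {})


class TestMapCoefficients:
    def test_round_trip_on_printed_coefficients(self):
        coeffs = fit_map_coefficients(synthetic_scan())
        assert coeffs.a == pytest.approx(0.312, abs=1e-9)
        # only a and the effective intercept a ln b + c are identifiable
        assert coeffs.intercept == pytest.approx(
            0.312 * np.log(1.693) + 0.861, abs=1e-9
        )
        assert coeffs.intercept == pytest.approx(1.0254, abs=2e-4)

    def test_affine_reparameterization_identity(self):
        coeffs = fit_map_coefficients(synthetic_scan(a=0.5, b=1.0, c=0.7))
        assert coeffs.a == pytest.approx(0.5, abs=1e-9)
        assert coeffs.c == pytest.approx(0.7, abs=1e-9)

    def test_model_scan_slope_near_printed_value(self, map_coeffs):
        assert abs(map_coeffs.a - 0.312) < 0.06

    def test_rejects_non_monotone_scan(self):
        scan = synthetic_scan()
        scan.results = list(reversed(scan.results))
        with pytest.raises(ValueError):
            fit_map_coefficients(scan)


class TestEstimateFcirrhosis:
    def test_printed_coefficient_evaluation(self):
        assert estimate_fcirrhosis(0.10, REFERENCE_COEFFICIENTS) == pytest.approx(
            0.307, abs=5e-4
        )

    def test_clamps_to_zero_for_low_r15(self):
        # raw value 0.312 ln(1.693*0.02)+0.861 = -0.195 -> clamped
        assert estimate_fcirrhosis(0.02, REFERENCE_COEFFICIENTS) == 0.0

    def test_map_root(self):
        r15_root = np.exp(-0.861 / 0.312) / 1.693
        assert r15_root == pytest.approx(0.0374, abs=1e-4)
        assert estimate_fcirrhosis(r15_root, REFERENCE_COEFFICIENTS) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rejects_nonpositive_r15(self):
        with pytest.raises(ValueError):
            estimate_fcirrhosis(0.0, REFERENCE_COEFFICIENTS)

    def test_round_trip_through_model_scan(self, cirrhosis_scan, map_coeffs):
        f_grid = np.arange(0.1, 0.81, 0.1)
        r15 = np.interp(f_grid, cirrhosis_scan.grid, cirrhosis_scan.values("r15"))
        est = estimate_fcirrhosis(r15, map_coeffs)
        assert np.max(np.abs(est - f_grid)) < 0.05


class TestPredictPostopR15:
    def test_zero_resection_identity(self, r15_surface):
        a = predict_postop_r15(0.4, 0.0, surface=r15_surface)
        b = r15_surface(0.4, 0.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_in_resection_and_cirrhosis(self, r15_surface):
        rr = np.linspace(0.0, 0.8, 9)
        vals = [predict_postop_r15(0.3, r, surface=r15_surface) for r in rr]
        assert np.all(np.diff(vals) >= -1e-12)
        fc = np.linspace(0.0, 0.8, 9)
        vals = [predict_postop_r15(f, 0.4, surface=r15_surface) for f in fc]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_surface_matches_direct_simulation(self, r15_surface, base_params):
        # grid nodes are exact simulations; interpolation only between nodes
        direct = predict_postop_r15(0.4, 0.3, surface=None, params=base_params)
        interp = r15_surface(0.4, 0.3)
        assert interp == pytest.approx(direct, rel=1e-6)


def _cohort():
    return [
        PatientRecord(1, 0.20, 0.5, True),
        PatientRecord(2, 0.10, 0.3, False),
        PatientRecord(3, 0.05, 0.2, True),
    ]


class TestBuildFeatures:
    def test_feature_definitions(self, r15_surface, map_coeffs):
        cohort = _cohort()
        X, y = build_features(cohort, "Data1A")
        assert X.shape == (3, 1)
        np.testing.assert_allclose(X[:, 0], [0.20, 0.10, 0.05])
        # non-survival is the positive class
        np.testing.assert_array_equal(y, [0, 1, 0])

        X, _ = build_features(cohort, "Data1B")
        assert X[0, 0] == pytest.approx(0.10)  # 0.20 * (1 - 0.5)

        X, _ = build_features(cohort, "Data2")
        assert X.shape == (3, 2)

        X, _ = build_features(cohort, "PBPK2", coeffs=REFERENCE_COEFFICIENTS)
        assert X[1, 0] == pytest.approx(0.307, abs=5e-4)
        assert X[1, 1] == pytest.approx(0.3)

    def test_pbpk1_uses_predicted_postop(self, r15_surface, map_coeffs):
        cohort = _cohort()
        X, _ = build_features(cohort, "PBPK1", coeffs=map_coeffs,
                              surface=r15_surface)
        assert X.shape == (3, 1)
        for p, x in zip(cohort, X[:, 0]):
            f = estimate_fcirrhosis(p.preop_r15, map_coeffs)
            assert x == pytest.approx(r15_surface(f, p.resection_rate), rel=1e-9)
            assert p.postop_r15_pred == pytest.approx(x)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            build_features(_cohort(), "Data3")

    def test_pbpk_requires_coefficients(self):
        with pytest.raises(ValueError):
            build_features(_cohort(), "PBPK1")


class TestMetrics:
    def test_confusion_example(self):
        # TP=3, FP=1, FN=1, TN=9
        y_true = np.array([1] * 4 + [0] * 10)
        y_pred = np.array([1, 1, 1, 0] + [1] + [0] * 9)
        m = confusion_metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(0.9)
        assert m["balanced_accuracy"] == pytest.approx(0.825)
        assert m["f1"] == pytest.approx(0.75)
        assert m["_confusion"] == (3, 1, 1, 9)

    def test_separable_case_perfect(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(5, 0.1, 30)])
        y = np.array([0] * 30 + [1] * 30)
        m = evaluate(X[:, None], y, seed=1, n_splits=25)
        assert m.full["roc_auc"] == pytest.approx(1.0)
        assert m.full["balanced_accuracy"] == pytest.approx(1.0)
        assert m.cv_mean["roc_auc"] == pytest.approx(1.0)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        m1 = evaluate(X, y, seed=11, n_splits=20)
        m2 = evaluate(X, y, seed=11, n_splits=20)
        assert m1.full == m2.full
        assert m1.cv_mean == m2.cv_mean
        assert m1.cv_sd == m2.cv_sd

    def test_requires_both_classes_and_size(self):
        X = np.zeros((30, 1))
        with pytest.raises(ValueError):
            evaluate(X, np.zeros(30, dtype=int), seed=0)
        with pytest.raises(ValueError):
            evaluate(np.zeros((10, 1)), np.array([0, 1] * 5), seed=0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.random(60)
        y = (x + 0.3 * rng.standard_normal(60) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, x) == pytest.approx(
            roc_auc_score(y, np.log(x + 1e-9)), abs=1e-12
        )


class TestCutoffScan:
    def test_extreme_cutoffs(self):
        rng = np.random.default_rng(2)
        feat = rng.random(50)
        y = (feat > 0.6).astype(int)
        df = cutoff_scan(feat, y, np.array([-1.0, 2.0]), seed=0, n_splits=10)
        low = df[df.cutoff == -1.0].iloc[0]
        high = df[df.cutoff == 2.0].iloc[0]
        assert low["recall"] == 1.0
        assert low["balanced_accuracy"] == pytest.approx(0.5)
        assert high["recall"] == 0.0

    def test_optimal_cutoff_recovered(self):
        rng = np.random.default_rng(4)
        feat = rng.uniform(0, 0.7, 300)
        y = (feat > 0.35).astype(int)
        cutoffs = np.arange(0.05, 0.66, 0.05)
        df = cutoff_scan(feat, y, cutoffs, seed=0, n_splits=10)
        best = df.loc[df["balanced_accuracy"].idxmax(), "cutoff"]
        assert best == pytest.approx(0.35, abs=0.051)


def test_patient_record_validation():
    with pytest.raises(ValueError):
        PatientRecord(1, 0.0, 0.5, True)
    with pytest.raises(ValueError):
        PatientRecord(1, 0.2, 0.95, True)
    with pytest.raises(ValueError):
        CirrhosisMapCoefficients(a=0.3, b=-1.0, c=0.8)
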