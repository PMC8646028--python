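"""Survival classification after partial hepatectomy.

The pipeline estimates an individual cirrhosis degree from the measured
preoperative ICG-R15 through the logarithmic map

    f_cirrhosis = a * ln(b * R15_preop) + c      (clamped to [0, 0.9])

whose coefficients are obtained by fitting the model-predicted dependency of
ICG-R15 on f_cirrhosis. Combining the estimate with the planned resection
rate, the PBPK model predicts the postoperative ICG-R15, which feeds the
classifiers. Five feature sets are compared: Data1A (preoperative R15),
Data1B (preoperative R15 x future liver remnant), Data2 (preoperative R15 +
resection rate), PBPK1 (model-predicted postoperative R15) and PBPK2
(estimated f_cirrhosis + resection rate). Non-survival is the positive
class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import ShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .pbpk_core import ModelParameters
from .protocols import standard_bolus
from .simulator import default_grid, simulate
from .nca import pk_parameters
from .scenarios import ScanTable

__all__ = [
    "MODEL_NAMES",
    "CirrhosisMapCoefficients",
    "PatientRecord",
    "CohortMetrics",
    "fit_map_coefficients",
    "estimate_fcirrhosis",
    "predict_postop_r15",
    "build_features",
    "evaluate",
    "cutoff_scan",
]

MODEL_NAMES = ("Data1A", "Data1B", "Data2", "PBPK1", "PBPK2")

#: Admissible range of the composite cirrhosis degree.
_F_RANGE = (0.0, 0.9)


@dataclass(frozen=True)
class CirrhosisMapCoefficients:
    """Coefficients of f_cirrhosis = a·ln(b·R15_preop) + c.

    Only ``a`` and the effective intercept ``a·ln(b) + c`` are identifiable
    from a scan fit; fitted coefficients are therefore reported with b = 1
    and c carrying the whole intercept.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")

    @property
    def intercept(self) -> float:
        """The identifiable combination a·ln(b) + c."""
        return self.a * np.log(self.b) + self.c


#: Coefficients printed for the original model (a=0.312, b=1.693, c=0.861).
REFERENCE_COEFFICIENTS = CirrhosisMapCoefficients(a=0.312, b=1.693, c=0.861)


@dataclass
class PatientRecord:
    """Classification inputs for one surgical patient."""

    patient_id: int
    preop_r15: float          # fraction
    resection_rate: float     # fraction
    survived: bool
    f_cirrhosis_est: float | None = None
    postop_r15_pred: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.preop_r15 < 1.0:
            raise ValueError(f"preop_r15 must lie in (0,1), got {self.preop_r15}")
        if not 0.0 <= self.resection_rate <= 0.9:
            raise ValueError(
                f"resection_rate must lie in [0, 0.9], got {self.resection_rate}"
            )


def fit_map_coefficients(scan: ScanTable) -> CirrhosisMapCoefficients:
    """Fit the logarithmic cirrhosis map to a model scan of R15 vs
    f_cirrhosis.

    Linear least squares of f on ln(R15) identifies the slope ``a`` and the
    effective intercept; returned as (a, b=1, c=intercept).
    """
    if scan.parameter not in ("f_cirrhosis",):
        raise ValueError("map fit requires an f_cirrhosis scan")
    f = np.asarray(scan.grid, dtype=float)
    r15 = scan.values("r15")
    if np.any(r15 <= 0):
        raise ValueError("scan contains non-positive R15 values")
    if not np.all(np.diff(r15) > 0):
        raise ValueError("R15 must increase monotonically along the scan")
    a, c = np.polyfit(np.log(r15), f, 1)
    return CirrhosisMapCoefficients(a=float(a), b=1.0, c=float(c))


def estimate_fcirrhosis(
    r15_preop: float | np.ndarray,
    coeffs: CirrhosisMapCoefficients,
) -> float | np.ndarray:
    """Cirrhosis degree estimated from preoperative ICG-R15, clamped to the
    admissible range [0, 0.9]."""
    r15 = np.asarray(r15_preop, dtype=float)
    if np.any(r15 <= 0):
        raise ValueError("R15_preop must be positive")
    raw = coeffs.a * np.log(coeffs.b * r15) + coeffs.c
    out = np.clip(raw, *_F_RANGE)
    return float(out) if np.isscalar(r15_preop) else out


def predict_postop_r15(
    f_cirrhosis,
    resection_rate,
    surface=None,
    params: ModelParameters | None = None,
) -> float | np.ndarray:
    """Model-predicted postoperative ICG-R15 for a cirrhosis degree and a
    resection rate.

    With ``surface`` (a precomputed :class:`~icgpbpk.cohort_synth.R15Surface`)
    the value is bilinearly interpolated; otherwise the standard bolus is
    simulated with both scenario parameters applied.
    """
    if surface is not None:
        return surface(f_cirrhosis, resection_rate)
    if params is None:
        params = ModelParameters()
    scenario = params.scenario.with_cirrhosis(float(f_cirrhosis))
    scenario = replace(scenario, resection_rate=float(resection_rate))
    tc = simulate(replace(params, scenario=scenario), standard_bolus(),
                  default_grid(60.0, 0.1))
    return pk_parameters(tc).r15


def build_features(
    cohort: list[PatientRecord],
    model: str,
    coeffs: CirrhosisMapCoefficients | None = None,
    surface=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and labels for one classification model.

    Labels encode non-survival as the positive class (1 = died). PBPK1/PBPK2
    require the cirrhosis-map coefficients; PBPK1 additionally predicts the
    postoperative R15 through the PBPK model (``surface`` strongly
    recommended for cohorts).
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown classification model: {model!r}")
    r15 = np.array([p.preop_r15 for p in cohort])
    rr = np.array([p.resection_rate for p in cohort])
    y = np.array([0 if p.survived else 1 for p in cohort])

    if model == "Data1A":
        X = r15[:, None]
    elif model == "Data1B":
        X = (r15 * (1.0 - rr))[:, None]
    elif model == "Data2":
        X = np.column_stack([r15, rr])
    else:
        if coeffs is None:
            raise ValueError(f"{model} requires cirrhosis-map coefficients")
        f_est = estimate_fcirrhosis(r15, coeffs)
        for p, f in zip(cohort, f_est):
            p.f_cirrhosis_est = float(f)
        if model == "PBPK2":
            X = np.column_stack([f_est, rr])
        else:  # PBPK1
            pred = np.array(
                [predict_postop_r15(f, r, surface=surface) for f, r in zip(f_est, rr)]
            )
            for p, v in zip(cohort, pred):
                p.postop_r15_pred = float(v)
            X = pred[:, None]
    return X, y


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class CohortMetrics:
    """Full-dataset and cross-validated classification metrics."""

    full: dict[str, float]
    cv_mean: dict[str, float]
    cv_sd: dict[str, float]
    n_splits: int
    n_skipped: int
    confusion: tuple[int, int, int, int]   # TP, FP, FN, TN on the full dataset
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr), full dataset
    model: str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "full": self.full,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "n_splits": self.n_splits,
            "n_skipped": self.n_skipped,
            "confusion_tp_fp_fn_tn": list(self.confusion),
        }


METRIC_NAMES = ("roc_auc", "balanced_accuracy", "f1", "precision", "recall", "npv")


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Confusion-matrix metrics with non-survival as the positive class.

    Empty denominators yield 0 (precision/F1 with no positive predictions)
    so that degenerate splits still produce finite numbers.
    """
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "balanced_accuracy": 0.5 * (recall + specificity),
        "f1": f1,
        "precision": precision,
        "recall": recall,
        "npv": npv,
        "_confusion": (tp, fp, fn, tn),
    }


def _make_classifier(random_state: int | None = None):
    """C-support vector classifier with a polynomial kernel on standardized
    features.

    Degree 3, C = 1, kernel scale from feature variance. The kernel is the
    inhomogeneous polynomial (gamma <x,x'> + 1)^3: including the lower-order
    terms makes hypothesis spaces nest across feature sets, so adding a
    feature can never shrink what the classifier can express.
    """
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="poly", degree=3, C=1.0, gamma="scale", coef0=1.0,
            random_state=random_state),
    )


def evaluate(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_splits: int = 200,
    test_size: float = 0.25,
) -> CohortMetrics:
    """Repeated random-split cross-validation of the survival classifier.

    200 ShuffleSplit iterations at a 75/25 train/test ratio; per-split
    confusion metrics and ROC AUC (from the continuous decision score) are
    aggregated as mean ± SD. A full-dataset fit-and-evaluate pass provides
    the headline value. Splits whose test set contains a single class are
    skipped and counted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        X = X.reshape(len(y), -1)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if len(y) < 20:
        raise ValueError("cohort too small (n < 20)")

    # full-dataset fit
    clf = _make_classifier(seed)
    clf.fit(X, y)
    score = clf.decision_function(X)
    full = confusion_metrics(y, clf.predict(X))
    confusion = full.pop("_confusion")
    full["roc_auc"] = float(roc_auc_score(y, score))
    fpr, tpr, _ = roc_curve(y, score)

    splitter = ShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
    per_split: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    skipped = 0
    for train, test in splitter.split(X):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            skipped += 1
            continue
        clf = _make_classifier(seed)
        clf.fit(X[train], y[train])
        m = confusion_metrics(y[test], clf.predict(X[test]))
        m.pop("_confusion")
        m["roc_auc"] = float(roc_auc_score(y[test], clf.decision_function(X[test])))
        for k, v in m.items():
            per_split[k].append(v)

    cv_mean = {k: float(np.mean(v)) for k, v in per_split.items()}
    cv_sd = {k: float(np.std(v)) for k, v in per_split.items()}
    return CohortMetrics(
        full={k: float(full[k]) for k in METRIC_NAMES},
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        n_splits=n_splits,
        n_skipped=skipped,
        confusion=confusion,
        roc=(fpr, tpr),
    )


def cutoff_scan(
    feature: np.ndarray,
    y: np.ndarray,
    cutoffs: np.ndarray,
    seed: int = 0,
    n_splits: int = 200,
    test_size: float = 0.25,
) -> pd.DataFrame:
    """Threshold-classifier metrics as a function of the decision cutoff.

    For each cutoff theta a patient is classified as non-survivor iff
    feature >= theta; metrics are evaluated on the full dataset and over
    repeated random test subsets (mean ± SD).
    """
    feature = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(y, dtype=int)
    cutoffs = np.asarray(cutoffs, dtype=float)
    splitter = ShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
    splits = [test for _, test in splitter.split(feature)]

    rows = []
    for theta in cutoffs:
        pred = (feature >= theta).astype(int)
        m_full = confusion_metrics(y, pred)
        m_full.pop("_confusion")
        per = {k: [] for k in m_full}
        for test in splits:
            if len(np.unique(y[test])) < 2:
                continue
            m = confusion_metrics(y[test], pred[test])
            m.pop("_confusion")
            for k, v in m.items():
                per[k].append(v)
        row = {"cutoff": theta}
        row.update({k: v for k, v in m_full.items()})
        row.update({f"{k}_cv_mean": float(np.mean(v)) for k, v in per.items()})
        row.update({f"{k}_cv_sd": float(np.std(v)) for k, v in per.items()})
        rows.append(row)
    return pd.DataFrame(rows)
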