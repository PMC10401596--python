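"""Evaluation quantities for GPR prediction models.

Regression models are scored by RMSE, MAE and the Spearman rank
correlation (CC) between predicted and measured gamma passing rates;
classification models by ROC/AUC, sensitivity and specificity with the
QA *fail* (GPR ≤ pass threshold) coded as the positive class 1.

The pass/fail rule reads "greater than 95 %" strictly: a field with GPR
exactly 95.0 % fails.  The boundary never occurs in continuous data but
the convention is fixed here once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

DEFAULT_PASS_THRESHOLD = 95.0


@dataclass(frozen=True)
class QARecord:
    """One QA sample: a field's complexity features, its measured (or
    simulated) gamma passing rate in percent, and the fail=1 / pass=0 label."""

    field_id: str
    features: dict[str, float]
    gpr: float
    label: int


def classify_labels(gprs, pass_threshold: float = DEFAULT_PASS_THRESHOLD) -> np.ndarray:
    """Binary QA outcome per field: 1 (fail) where GPR ≤ threshold, else 0 (pass)."""
    gprs = np.asarray(gprs, dtype=float)
    if not np.all(np.isfinite(gprs)):
        raise ValueError("GPR values must be finite")
    return (gprs <= pass_threshold).astype(int)


def interpret_cc(cc: float) -> str:
    """Customary correlation bands: >0.8 high, 0.4–0.8 moderate, <0.4 low."""
    a = abs(cc)
    if a > 0.8:
        return "high"
    if a > 0.4:
        return "moderate"
    return "low"


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """RMSE, MAE (both in GPR percentage points), Spearman CC and its p-value.

    The Spearman correlation uses mid-ranks for ties and the
    t-approximation for the p-value.  A constant input vector leaves the
    correlation undefined; it is reported as NaN with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if len(y_true) < 3:
        raise ValueError("need at least 3 samples")
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    mae = float(np.mean(np.abs(y_pred - y_true)))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant vector: Spearman CC undefined", stacklevel=2)
        cc, p = float("nan"), float("nan")
    else:
        res = stats.spearmanr(y_true, y_pred)
        cc, p = float(res.statistic), float(res.pvalue)
    return {"rmse": rmse, "mae": mae, "cc": cc, "p": p}


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes (pass and fail) must be present")


def roc_curve(scores, labels) -> np.ndarray:
    """ROC points (FPR, TPR) swept over all distinct score thresholds.

    Higher score means more likely to fail (label 1).  The returned
    array runs monotonically from (0, 0) to (1, 1).
    """
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, _ = _skm.roc_curve(labels, np.asarray(scores, dtype=float), pos_label=1)
    return np.column_stack([fpr, tpr])


def auc(scores, labels) -> float:
    """Area under the ROC curve; equals the Mann–Whitney pairwise
    probability that a random fail outscores a random pass, ties ½."""
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sens_spec(pred_labels, true_labels) -> tuple[float, float]:
    """Sensitivity = TP/(TP+FN) over true fails; specificity = TN/(TN+FP) over true passes."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    _check_two_classes(true)
    tp = int(np.sum((pred == 1) & (true == 1)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def univariate_analysis(records, feature_name: str,
                        pass_threshold: float = DEFAULT_PASS_THRESHOLD) -> dict[str, float]:
    """Single-feature screen: Spearman CC of the feature against GPR (sign
    preserved), its p-value, and the AUC of the feature used as the sole
    fail score.

    The AUC orientation is chosen so that AUC ≥ 0.5 and reported via
    ``orientation`` (+1: larger feature values indicate fail; −1: smaller
    values do).
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    x = np.array([r.features[feature_name] for r in records], dtype=float)
    gpr = np.array([r.gpr for r in records], dtype=float)
    labels = np.array([r.label for r in records], dtype=int)
    _check_two_classes(labels)
    if np.ptp(x) == 0:
        warnings.warn(f"constant feature {feature_name}: univariate screen undefined", stacklevel=2)
        return {"cc": float("nan"), "p": float("nan"), "auc": float("nan"), "orientation": 0}
    res = stats.spearmanr(x, gpr)
    a = auc(x, labels)
    orientation = 1 if a >= 0.5 else -1
    return {
        "cc": float(res.statistic),
        "p": float(res.pvalue),
        "auc": a if a >= 0.5 else 1.0 - a,
        "orientation": orientation,
    }


def records_to_frame(records):
    """QA records as a DataFrame: field_id index, 21 feature columns, gpr_percent, label."""
    import pandas as pd
    from planqa.features import FEATURE_NAMES

    rows = []
    for r in records:
        row = {"field_id": r.field_id}
        row.update({k: r.features[k] for k in FEATURE_NAMES})
        row["gpr_percent"] = r.gpr
        row["label"] = r.label
        rows.append(row)
    return pd.DataFrame(rows).set_index("field_id")


def frame_to_records(df) -> list[QARecord]:
    from planqa.features import FEATURE_NAMES

    return [
        QARecord(
            field_id=str(idx),
            features={k: float(row[k]) for k in FEATURE_NAMES},
            gpr=float(row["gpr_percent"]),
            label=int(row["label"]),
        )
        for idx, row in df.iterrows()
    ]
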