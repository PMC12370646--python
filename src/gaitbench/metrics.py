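"""Ordinal-classification and regression evaluation metrics.

Implements the evaluation conventions of clinical ordinal score
prediction: per-class precision/recall/F1 with explicit UNDEFINED
handling, support-weighted and macro F1, absolute and acceptable accuracy
(ACC+-0 / ACC+-1), quadratically weighted Cohen's kappa with the standard
interpretation bands, and MAE / RMSE / Spearman for subscale regression.

UNDEFINED conventions (validated by reconstruction against published
per-class tables):

* precision is UNDEFINED when a class is never predicted; recall is 0
  when the class occurs but is never hit, UNDEFINED when it never occurs;
  F1 is defined only when precision and recall are both defined and their
  sum is positive;
* weighted F1 treats an UNDEFINED class F1 as 0 while keeping its support
  in the denominator;
* macro F1 averages only the classes whose F1 is defined.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as _stats

UNDEFINED = None

KAPPA_BANDS = (
    (-np.inf, 0.0, "poor agreement"),
    (0.0, 0.21, "slight agreement"),
    (0.21, 0.41, "fair agreement"),
    (0.41, 0.61, "moderate agreement"),
    (0.61, 0.81, "substantial agreement"),
    (0.81, np.inf, "almost perfect agreement"),
)

CORRELATION_BANDS = (
    (0.0, 0.10, "negligible correlation"),
    (0.10, 0.40, "weak correlation"),
    (0.40, 0.70, "moderate correlation"),
    (0.70, 0.90, "strong correlation"),
    (0.90, np.inf, "very strong correlation"),
)


def kappa_band(kw: float) -> str:
    for lo, hi, name in KAPPA_BANDS:
        if lo <= kw < hi:
            return name
    raise ValueError(f"kappa {kw} outside bands")


def correlation_band(r: float) -> str:
    for lo, hi, name in CORRELATION_BANDS:
        if lo <= abs(r) < hi:
            return name
    raise ValueError(f"correlation {r} outside bands")


@dataclasses.dataclass
class ClassMetrics:
    label: str
    precision: float | None
    recall: float | None
    f1: float | None
    support: int


@dataclasses.dataclass
class ItemReport:
    """Aggregate ordinal metrics for one clinical item."""

    weighted_f1: float
    macro_f1: float | None
    acc_exact: float  # percent
    acc_within1: float  # percent
    kappa_w: float | None
    kappa_band: str | None
    per_class: list[ClassMetrics]
    n: int

    def to_dict(self) -> dict:
        return {
            "weighted_f1": self.weighted_f1,
            "macro_f1": self.macro_f1,
            "acc_exact": self.acc_exact,
            "acc_within1": self.acc_within1,
            "kappa_w": self.kappa_w,
            "kappa_band": self.kappa_band,
            "n": self.n,
            "per_class": [dataclasses.asdict(c) for c in self.per_class],
        }


@dataclasses.dataclass
class RegressionReport:
    mae: float
    rmse: float
    spearman_r: float
    spearman_p: float
    band: str
    n: int


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """M x M count matrix, rows = true merged level, columns = predicted."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _f1_from(precision, recall):
    if precision is UNDEFINED or recall is UNDEFINED:
        return UNDEFINED
    if precision + recall <= 0:
        return UNDEFINED
    return 2.0 * precision * recall / (precision + recall)


def per_class_metrics(cm: np.ndarray, labels: list[str] | None = None) -> list[ClassMetrics]:
    """Precision/recall/F1 per class with the UNDEFINED conventions."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    m = cm.shape[0]
    labels = labels or [str(i) for i in range(m)]
    out = []
    for c in range(m):
        tp = cm[c, c]
        col = cm[:, c].sum()
        row = cm[c, :].sum()
        precision = UNDEFINED if col == 0 else tp / col
        recall = UNDEFINED if row == 0 else tp / row
        out.append(
            ClassMetrics(labels[c], precision, recall, _f1_from(precision, recall), int(row))
        )
    return out


def weighted_f1(class_metrics: list[ClassMetrics]) -> float:
    """Support-weighted F1; UNDEFINED class F1 contributes 0 but its
    support stays in the denominator."""
    total = sum(c.support for c in class_metrics)
    if total <= 0:
        raise ValueError("no true instances")
    acc = sum(c.f1 * c.support for c in class_metrics if c.f1 is not UNDEFINED)
    return acc / total


def macro_f1(class_metrics: list[ClassMetrics]) -> float:
    """Unweighted mean of the defined class F1 scores."""
    defined = [c.f1 for c in class_metrics if c.f1 is not UNDEFINED]
    if not defined:
        raise ValueError("macro F1 undefined: no class has a defined F1")
    return float(np.mean(defined))


def acc_within(cm: np.ndarray, k: int) -> float:
    """Percent of cases within ``k`` merged levels of the true level."""
    cm = np.asarray(cm)
    n = cm.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    i, j = np.indices(cm.shape)
    return 100.0 * cm[np.abs(i - j) <= k].sum() / n


def weighted_kappa(cm: np.ndarray) -> float | None:
    """Cohen's kappa with quadratic disagreement weights.

    ``w_ij = ((i - j) / (M - 1))^2``; larger ordinal disagreements are
    penalised more.  Returns UNDEFINED when chance agreement is exact
    (degenerate marginals make kappa ill-defined).
    """
    cm = np.asarray(cm, dtype=float)
    m = cm.shape[0]
    if m < 2:
        raise ValueError("weighted kappa needs at least 2 classes")
    n = cm.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    i, j = np.indices((m, m))
    w = ((i - j) / (m - 1)) ** 2
    obs = (w * cm).sum() / n
    expected = np.outer(cm.sum(axis=1), cm.sum(axis=0)) / (n * n)
    exp = (w * expected).sum()
    if exp == 0:
        return UNDEFINED
    return 1.0 - obs / exp


def item_report(cm: np.ndarray, labels: list[str] | None = None) -> ItemReport:
    """Full aggregate report from a confusion matrix."""
    pcm = per_class_metrics(cm, labels)
    kw = weighted_kappa(cm)
    try:
        macro = macro_f1(pcm)
    except ValueError:
        macro = UNDEFINED
    return ItemReport(
        weighted_f1=weighted_f1(pcm),
        macro_f1=macro,
        acc_exact=acc_within(cm, 0),
        acc_within1=acc_within(cm, 1),
        kappa_w=kw,
        kappa_band=None if kw is UNDEFINED else kappa_band(kw),
        per_class=pcm,
        n=int(np.asarray(cm).sum()),
    )


def regression_metrics(y_true, y_pred) -> RegressionReport:
    """MAE, RMSE and Spearman rank correlation (average ranks on ties)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    rho, p = _stats.spearmanr(y_true, y_pred)
    return RegressionReport(mae, rmse, float(rho), float(p), correlation_band(rho), y_true.size)


def feature_score_correlation(feature_values, item_scores) -> tuple[float | None, float | None]:
    """Spearman R (two-sided p) between a feature and an ordinal score."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(item_scores, dtype=float)
    if x.size < 10:
        raise ValueError("need n >= 10")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return UNDEFINED, UNDEFINED
    rho, p = _stats.spearmanr(x, y)
    return float(rho), float(p)


def reconstruct_from_table(
    precision: list[float | None],
    recall: list[float],
    support: list[int],
    warn_tol: float = 0.45,
) -> dict:
    """Aggregate metrics recomputed from printed per-class values.

    Given per-class precision (possibly UNDEFINED), recall and support as
    printed in an evaluation table, recompute per-class F1, weighted F1,
    macro F1 and ACC+-0 (via TP_c = round(recall_c * N_c)).  A recall*N
    further than ``warn_tol`` from an integer indicates a printed rounding
    inconsistency and triggers a warning entry.
    """
    if len(precision) != len(recall) or len(recall) != len(support):
        raise ValueError("per-class lists must have equal length")
    if any(n <= 0 or int(n) != n for n in support):
        raise ValueError("supports must be positive integers")
    warnings = []
    cms = []
    tps = []
    for c, (p, r, n) in enumerate(zip(precision, recall, support)):
        tp_raw = r * n
        tp = round(tp_raw)
        if abs(tp_raw - tp) > warn_tol:
            warnings.append(f"class {c}: recall*N = {tp_raw:.3f} is not near an integer")
        tps.append(tp)
        cms.append(ClassMetrics(str(c), p, r, _f1_from(p, r), int(n)))
    total = sum(support)
    return {
        "per_class_f1": [c.f1 for c in cms],
        "weighted_f1": weighted_f1(cms),
        "macro_f1": macro_f1(cms),
        "acc_exact": 100.0 * sum(tps) / total,
        "warnings": warnings,
    }
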