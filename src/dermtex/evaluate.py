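"""Evaluation: confusion matrix, classification metrics, ROC/AUC, and
rank-sum comparison of class-conditional feature distributions.

Melanoma is the positive class throughout.  Specificity is the true
negative rate TN/(TN+FP) and the false positive rate is its complement.
Metrics whose denominator is zero are reported as NaN (an explicit
"undefined" marker) rather than silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

POSITIVE = "melanoma"
NEGATIVE = "nevus"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with melanoma as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Accuracy, sensitivity/specificity and per-class precision/recall/F1."""

    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    precision: dict[str, float]
    recall: dict[str, float]
    f_score: dict[str, float]
    support: dict[str, int]


@dataclass(frozen=True)
class ROCCurve:
    """(FPR, TPR) sweep and the trapezoidal area under it."""

    points: np.ndarray  # (k, 2) array of (fpr, tpr)
    auc: float


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney rank-sum statistic (U of the first sample) and
    two-sided p-value."""

    U: float
    p_value: float


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Exact confusion counts from label sequences."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    known = {POSITIVE, NEGATIVE}
    unknown = (set(np.unique(yt)) | set(np.unique(yp))) - known
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}; expected {sorted(known)}")
    pos_t = yt == POSITIVE
    pos_p = yp == POSITIVE
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def _f1(precision: float, recall: float) -> float:
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Derive the standard binary metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec_pos = _ratio(cm.tp, cm.tp + cm.fp)
    prec_neg = _ratio(cm.tn, cm.tn + cm.fn)
    precision = {POSITIVE: prec_pos, NEGATIVE: prec_neg}
    recall = {POSITIVE: sens, NEGATIVE: spec}
    f_score = {POSITIVE: _f1(prec_pos, sens), NEGATIVE: _f1(prec_neg, spec)}
    support = {POSITIVE: cm.tp + cm.fn, NEGATIVE: cm.tn + cm.fp}
    return MetricReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        fpr=1.0 - spec if not np.isnan(spec) else float("nan"),
        precision=precision, recall=recall, f_score=f_score, support=support,
    )


def roc_auc(y_true, scores) -> ROCCurve:
    """ROC curve by threshold sweep over the unique scores, AUC by the
    trapezoidal rule; tied scores collapse into one step."""
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    labels = np.unique(yt)
    if len(labels) < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, _ = _sk_roc_curve(yt, s, pos_label=POSITIVE,
                                drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=np.column_stack([fpr, tpr]), auc=auc)


def mann_whitney(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n1*n2 <= 200 and there are no cross-sample ties;
    normal approximation with tie correction otherwise.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([xa, ya]))) < xa.size + ya.size
    method = "exact" if (xa.size * ya.size <= 200 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return RankTestResult(U=float(res.statistic), p_value=float(res.pvalue))


@dataclass(frozen=True)
class ClassSummary:
    """One row of a per-feature class comparison: class-conditional mean
    and SD plus the two-sided rank-sum p-value."""

    feature: str
    mean: dict[str, float]
    sd: dict[str, float]
    p_value: float


def class_summary(ds, feature: str) -> ClassSummary:
    """Class-conditional mean +/- SD of one feature with a Mann-Whitney p.

    SD uses the population convention, consistent with the first-order
    moments elsewhere in the package.
    """
    if feature not in ds.feature_names:
        raise ValueError(f"unknown feature '{feature}'")
    col = ds.df[feature].to_numpy(dtype=np.float64)
    lab = ds.y
    groups = {}
    for cls in (NEGATIVE, POSITIVE):
        vals = col[lab == cls]
        if vals.size == 0:
            raise ValueError(f"class '{cls}' is absent from the dataset")
        groups[cls] = vals
    test = mann_whitney(groups[POSITIVE], groups[NEGATIVE])
    return ClassSummary(
        feature=feature,
        mean={c: float(v.mean()) for c, v in groups.items()},
        sd={c: float(v.std()) for c, v in groups.items()},
        p_value=test.p_value,
    )


def five_number_summary(values) -> dict[str, float]:
    """Min, quartiles and max — the boxplot statistics of one sample."""
    v = np.asarray(values, dtype=np.float64)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"min": float(v.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v.max())}


def majority_vote(image_ids, y_true, y_pred) -> tuple[list, list]:
    """Collapse patch-level predictions to image level by majority vote.

    Ties break toward melanoma (the positive class is never missed by a
    coin flip).  Returns image-level (y_true, y_pred) lists.
    """
    ids = np.asarray(image_ids)
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    img_true, img_pred = [], []
    for uid in np.unique(ids):
        sel = ids == uid
        img_true.append(yt[sel][0])
        votes = int(np.sum(yp[sel] == POSITIVE))
        img_pred.append(POSITIVE if votes * 2 >= sel.sum() else NEGATIVE)
    return img_true, img_pred
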