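"""ROC/Youden calibration, confusion-matrix metrics, two-level evaluation.

Evaluation happens at two levels.  At the *image* level each 85-beat
scattergram gets an AF probability and is thresholded at the calibrated
image cutoff.  At the *record* level a recording's "AF burden" is the
fraction of its (non-overlapping) images classified AF; two further
cutoffs on that fraction give the three-way decision:

    burden <  c_af                     ->  non-AF record
    c_af <= burden < c_persistent      ->  paroxysmal AF
    burden >= c_persistent             ->  persistent AF

All three cutoffs are calibrated by maximizing the Youden index
J = sensitivity + specificity - 1 over a ROC curve.  AF is always the
positive class; likelihood ratios that would divide by zero are reported
as an explicit NA marker (``None``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import BeatClass, RecordClass

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROCCurve",
    "ThresholdSet",
    "RecordAggregation",
    "confusion_matrix",
    "classification_metrics",
    "roc_curve",
    "auc",
    "youden_cutoff",
    "record_score",
    "classify_record",
    "calibrate_thresholds",
    "evaluate_two_level",
    "TwoLevelReport",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with AF as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    """Sensitivity/specificity family; ``None`` marks an undefined ratio (NA)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float
    ppv: Optional[float]
    npv: Optional[float]
    lr_plus: Optional[float]
    lr_minus: Optional[float]
    auc: Optional[float] = None
    confusion: Optional[ConfusionMatrix] = None

    def rounded(self, ndigits: int = 3) -> dict[str, Optional[float]]:
        """Presentation rounding; NA stays ``None``."""
        out = {}
        for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv",
                  "lr_plus", "lr_minus", "auc"):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, ndigits)
        return out


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    """Count TP/FN/FP/TN; labels may be BeatClass, bool, or 0/1."""
    t = _as_binary(true_labels)
    p = _as_binary(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if len(t) == 0:
        raise ValueError("empty label sequences")
    return ConfusionMatrix(
        tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
        fp=int(np.sum(~t & p)), tn=int(np.sum(~t & ~p)),
    )


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray([
        1 if (lbl is BeatClass.AF or lbl == BeatClass.AF or lbl is True or lbl == 1)
        else 0
        for lbl in labels
    ], dtype=bool)
    return arr


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def classification_metrics(cm: ConfusionMatrix,
                           auc_value: Optional[float] = None) -> MetricsReport:
    """Standard definitions; rounding happens only at presentation.

    Sen = tp/(tp+fn), Spe = tn/(tn+fp), Acc = (tp+tn)/n, PPV = tp/(tp+fp),
    NPV = tn/(tn+fn), +LR = Sen/(1-Spe) (NA when Spe = 1), -LR = (1-Sen)/Spe
    (NA when Spe = 0).
    """
    sen = _ratio(cm.tp, cm.tp + cm.fn)
    spe = _ratio(cm.tn, cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    lr_plus = None
    lr_minus = None
    if sen is not None and spe is not None:
        lr_plus = None if spe == 1.0 else sen / (1.0 - spe)
        lr_minus = None if spe == 0.0 else (1.0 - sen) / spe
    return MetricsReport(sensitivity=sen, specificity=spe, accuracy=acc,
                         ppv=ppv, npv=npv, lr_plus=lr_plus, lr_minus=lr_minus,
                         auc=auc_value, confusion=cm)


# ---------------------------------------------------------------------------
# ROC / AUC / Youden
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """ROC over all distinct score thresholds (prediction rule: score >= t).

    ``thresholds`` is descending and includes a sentinel above the max
    score (operating point (0,0)) and one at the min score (point (1,1)).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if not (len(self.thresholds) == len(self.fpr) == len(self.tpr)):
            raise ValueError("curve arrays must have equal length")
        if self.fpr[0] != 0 or self.tpr[0] != 0 or self.fpr[-1] != 1 or self.tpr[-1] != 1:
            raise ValueError("curve must run from (0,0) to (1,1)")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")


def roc_curve(scores: Sequence[float], labels: Sequence) -> ROCCurve:
    """ROC from scores and binary labels (both classes required)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve requires both classes")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # collapse ties: cumulative counts at each distinct score
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    last_of_group = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp_cum = np.cumsum(y_sorted)[last_of_group]
    fp_cum = np.cumsum(~y_sorted)[last_of_group]
    thr = np.concatenate([[s_sorted[0] + 1.0], s_sorted[last_of_group]])
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area; equals the tie-adjusted pairwise-win probability."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_cutoff(curve: ROCCurve) -> float:
    """Threshold maximizing J = TPR - FPR; ties go to the higher threshold.

    Candidates are the distinct observed scores plus the sentinel one unit
    above the maximum (the all-negative operating point (0,0)); the first
    argmax in descending-threshold order resolves ties toward the more
    specific cutoff.
    """
    j = curve.tpr - curve.fpr
    # first index within float tolerance of the max = highest tied threshold
    k = int(np.argmax(j >= j.max() - 1e-12))
    return float(curve.thresholds[k])


# ---------------------------------------------------------------------------
# record-level aggregation and three-way decision
# ---------------------------------------------------------------------------

class RecordAggregation(str, enum.Enum):
    """How per-image scores collapse into one record-level value."""

    AF_FRACTION = "af_fraction"   # fraction of images with score >= image cutoff
    MEAN_SCORE = "mean_score"     # mean raw probability (alternative)


@dataclass(frozen=True)
class ThresholdSet:
    """The three calibrated cutoffs driving deployment decisions."""

    ls_cutoff: float
    record_af_cutoff: float
    persistent_cutoff: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.record_af_cutoff <= self.persistent_cutoff <= 1.0):
            raise ValueError(
                "need 0 <= record_af_cutoff <= persistent_cutoff <= 1, got "
                f"{self.record_af_cutoff} / {self.persistent_cutoff}"
            )


def record_score(image_scores: Sequence[float], ls_cutoff: float,
                 aggregation: RecordAggregation = RecordAggregation.AF_FRACTION) -> float:
    """Collapse a record's image scores into its AF burden in [0, 1]."""
    s = np.asarray(image_scores, dtype=float)
    if s.size == 0:
        raise ValueError("record has no image scores")
    if aggregation is RecordAggregation.MEAN_SCORE:
        return float(np.clip(s.mean(), 0.0, 1.0))
    return float(np.mean(s >= ls_cutoff))


def classify_record(fraction: float, thresholds: ThresholdSet) -> RecordClass:
    """Three-way decision on the AF burden fraction (half-open intervals)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction < thresholds.record_af_cutoff:
        return RecordClass.NON_AF
    if fraction < thresholds.persistent_cutoff:
        return RecordClass.PAROXYSMAL_AF
    return RecordClass.PERSISTENT_AF


def calibrate_thresholds(
    image_scores: Sequence[float],
    image_labels: Sequence,
    record_fractions_fn,
    record_truths: Sequence[RecordClass],
) -> ThresholdSet:
    """Calibrate the three cutoffs by Youden-maximized ROC analyses.

    1. image cutoff: ROC of image scores against image AF labels;
    2. record AF cutoff: ROC of record burden fractions (computed at the
       image cutoff via ``record_fractions_fn(ls_cutoff)``) against
       AF-vs-non-AF record truth;
    3. persistent cutoff: same fractions restricted to AF records,
       persistent vs paroxysmal.

    ``record_fractions_fn`` maps an image cutoff to one burden fraction
    per record (aligned with ``record_truths``).  The ordering invariant
    record_af_cutoff <= persistent_cutoff is enforced by clipping the AF
    cutoff down to the persistent one if the two ROC analyses cross.
    """
    ls_cutoff = float(np.clip(youden_cutoff(roc_curve(image_scores, image_labels)), 0.0, 1.0))

    fractions = np.asarray(record_fractions_fn(ls_cutoff), dtype=float)
    truths = list(record_truths)
    if len(fractions) != len(truths):
        raise ValueError("record fractions and truths must align")
    is_af = np.asarray([t is not RecordClass.NON_AF for t in truths], dtype=bool)
    if is_af.all() or not is_af.any():
        raise ValueError("record calibration requires both AF and non-AF records")
    rec_cut = float(np.clip(youden_cutoff(roc_curve(fractions, is_af)), 0.0, 1.0))

    af_fracs = fractions[is_af]
    af_truths = [t for t in truths if t is not RecordClass.NON_AF]
    is_persistent = np.asarray([t is RecordClass.PERSISTENT_AF for t in af_truths], dtype=bool)
    if is_persistent.all() or not is_persistent.any():
        raise ValueError("persistent-cutoff calibration requires both AF subtypes")
    pers_cut = float(np.clip(youden_cutoff(roc_curve(af_fracs, is_persistent)), 0.0, 1.0))

    rec_cut = min(rec_cut, pers_cut)
    return ThresholdSet(ls_cutoff=ls_cutoff, record_af_cutoff=rec_cut,
                        persistent_cutoff=pers_cut)


@dataclass
class TwoLevelReport:
    """Image-level binary report + one-vs-rest record-level reports."""

    image_level: MetricsReport
    record_level: dict[RecordClass, MetricsReport]
    record_accuracy: float = 0.0   # plain 3-class accuracy over records
    record_predictions: dict[str, RecordClass] = field(default_factory=dict)
    record_fractions: dict[str, float] = field(default_factory=dict)


def evaluate_two_level(
    image_scores: Sequence[float],
    image_labels: Sequence,
    thresholds: ThresholdSet,
    record_scores: Mapping[str, Sequence[float]],
    record_truths: Mapping[str, RecordClass],
    aggregation: RecordAggregation = RecordAggregation.AF_FRACTION,
) -> TwoLevelReport:
    """Two-level performance evaluation.

    Image level: scores thresholded at ``ls_cutoff`` against image labels,
    with AUC.  Record level: each record's images collapse to an AF burden,
    the three-way rule is applied, and one one-vs-rest report per class is
    computed (AF subtype reports can print NA likelihood ratios when a
    class is perfectly separated, mirroring degenerate denominators).
    """
    scores = np.asarray(image_scores, dtype=float)
    if scores.size == 0 or not record_scores:
        raise ValueError("empty evaluation set")
    y_img = _as_binary(image_labels)
    pred_img = scores >= thresholds.ls_cutoff
    img_auc = auc(roc_curve(scores, y_img)) if (y_img.any() and not y_img.all()) else None
    image_report = classification_metrics(confusion_matrix(y_img, pred_img), img_auc)

    preds: dict[str, RecordClass] = {}
    fracs: dict[str, float] = {}
    for rid, s in record_scores.items():
        frac = record_score(s, thresholds.ls_cutoff, aggregation)
        fracs[rid] = frac
        preds[rid] = classify_record(frac, thresholds)

    rids = list(record_scores.keys())
    truth_vec = [record_truths[r] for r in rids]
    pred_vec = [preds[r] for r in rids]
    per_class: dict[RecordClass, MetricsReport] = {}
    for cls in RecordClass:
        cm = confusion_matrix([t is cls for t in truth_vec],
                              [p is cls for p in pred_vec])
        per_class[cls] = classification_metrics(cm)
    acc3 = float(np.mean([t is p for t, p in zip(truth_vec, pred_vec)]))
    return TwoLevelReport(image_level=image_report, record_level=per_class,
                          record_accuracy=acc3,
                          record_predictions=preds, record_fractions=fracs)
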