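"""ROC evaluation of the subject-level mean alpha power ratio as a biomarker.

The orientation is fixed by the directional hypothesis: higher log ratio
(more slow alpha) means more patient-like, so a subject is classified as a
patient when their score meets or exceeds the threshold.  The AUC is the
trapezoidal area, which for this construction equals the Mann-Whitney
statistic U/(n_pos * n_neg) with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ratio import AlphaRatioTable, global_mean_ratio
from .stats import TestResult, unpaired_t


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    positive_label: str = "patient"


def roc_curve(scores, labels, positive_label: str = "patient") -> RocResult:
    """ROC curve for rule ``score >= threshold => positive``.

    ``labels`` is boolean (True = positive class).  Thresholds descend from
    a +inf sentinel (nothing classified positive) through each unique score,
    so tied scores share one operating point and the curve runs from (0,0)
    to (1,1).
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=bool).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s >= t
        tpr[i] = np.sum(pred & y) / n_pos
        fpr[i] = np.sum(pred & ~y) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
        n_pos=n_pos, n_neg=n_neg, positive_label=positive_label,
    )


@dataclass(frozen=True)
class BiomarkerEvaluation:
    roc: RocResult
    mean_patient: float
    mean_control: float
    t_test: TestResult


def evaluate_biomarker(table: AlphaRatioTable) -> BiomarkerEvaluation:
    """Mean-ratio-per-subject ROC plus the patient-vs-control unpaired t."""
    scores = global_mean_ratio(table)
    is_patient = table.group_mask("left_TLE", "right_TLE")
    if is_patient.sum() < 2 or (~is_patient).sum() < 2:
        raise ValueError("evaluate_biomarker needs >= 2 subjects per class")
    roc = roc_curve(scores, is_patient)
    t_res = unpaired_t(scores[is_patient], scores[~is_patient])
    return BiomarkerEvaluation(
        roc=roc,
        mean_patient=float(scores[is_patient].mean()),
        mean_control=float(scores[~is_patient].mean()),
        t_test=t_res,
    )
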