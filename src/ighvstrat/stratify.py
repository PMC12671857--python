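"""ROC-based stratification of patients by V-gene usage.

The usage fraction of IGHV4-34 in unswitched-memory B cells is scored
against the binary low-complement label: the classification rule is
``usage >= threshold -> predicted low complement``. Sensitivity and
specificity are evaluated at every distinct observed usage value (plus a
+inf sentinel, the all-negative rule); the AUC is the trapezoidal area,
which for this construction equals the tie-corrected rank (Mann-Whitney)
statistic. The operating cutoff is the threshold whose (1-spec, sens)
point lies closest to the top-left corner (0, 1) in Euclidean distance;
Youden's J argmax is also reported for comparison but is never the
selector, since the two can disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError

__all__ = ["RocResult", "roc_curve", "select_cutoff", "fit_roc", "assign_groups"]


@dataclass
class RocResult:
    """ROC curve plus, after cutoff selection, the chosen operating point."""

    thresholds: np.ndarray  # descending; thresholds[0] = +inf sentinel
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    cutoff: float | None = None
    cutoff_sens: float | None = None
    cutoff_spec: float | None = None
    youden_cutoff: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sens": self.sens, "spec": self.spec}
        )


def roc_curve(scores, labels) -> RocResult:
    """ROC of ``scores`` against boolean ``labels`` (True = positive class).

    Tied scores move the curve diagonally (one simultaneous
    vertical+horizontal step), so the trapezoidal AUC carries the standard
    half-credit for ties. Raises if only one class is present or any score
    is non-finite.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be paired")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError(
            "ROC undefined: both classes must be present in the labels"
        )
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    # predicted positive <=> score >= threshold
    tp = np.array([(labels & (scores >= t)).sum() for t in thresholds])
    fp = np.array([(~labels & (scores >= t)).sum() for t in thresholds])
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return RocResult(thresholds, sens, spec, auc, n_pos, n_neg)


def _closest_to_corner_index(roc: RocResult) -> int:
    d = np.hypot(1.0 - roc.sens, 1.0 - roc.spec)
    best = d.min()
    # thresholds are descending, so the last index attaining the minimum is
    # the lowest threshold (highest sensitivity) — the documented tie-break
    return int(np.flatnonzero(d <= best + 1e-12)[-1])


def select_cutoff(roc: RocResult) -> float:
    """Threshold minimizing the distance to the (0, 1) ROC corner.

    Ties are broken toward the lower threshold, i.e. the more sensitive
    operating point.
    """
    return float(roc.thresholds[_closest_to_corner_index(roc)])


def fit_roc(scores, labels) -> RocResult:
    """ROC curve with the closest-to-corner cutoff and its operating point."""
    roc = roc_curve(scores, labels)
    i = _closest_to_corner_index(roc)
    roc.cutoff = float(roc.thresholds[i])
    roc.cutoff_sens = float(roc.sens[i])
    roc.cutoff_spec = float(roc.spec[i])
    j = roc.sens + roc.spec - 1.0
    roc.youden_cutoff = float(roc.thresholds[np.flatnonzero(j >= j.max() - 1e-12)[-1]])
    return roc


def assign_groups(usages, cutoff: float) -> pd.DataFrame:
    """Assign HIGH (usage >= cutoff) / LOW groups per patient.

    ``usages`` maps patient_id -> USM usage fraction. Patients with a
    missing (NaN) usage are reported with group <NA>, never defaulted into
    a group. Usage exactly at the cutoff is HIGH.
    """
    usages = pd.Series(usages, dtype=float)
    group = pd.Series(pd.NA, index=usages.index, dtype="object")
    group[usages >= cutoff] = "HIGH"
    group[usages < cutoff] = "LOW"
    return pd.DataFrame(
        {"patient_id": usages.index, "usage": usages.to_numpy(), "group": group.to_numpy()}
    )
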