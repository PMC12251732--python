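"""Evaluation against the Morse Fall Scale (MFS).

The MFS total score (0–125 points) is the clinical ground truth.  It is
thresholded into three risk levels — Low (< 25), Moderate (25–45
inclusive), High (> 45) — with numeric equivalents 0.3 / 0.6 / 0.9 used
when a score on the model's [0, 1] axis is needed.

Predictions are scored two ways:

* **binary confusion matrix** after collapsing levels into at-risk
  (Moderate or High, the positive class) vs not-at-risk (Low), from
  which accuracy, sensitivity and specificity are computed;
* **multi-class exact-match agreement**, reported alongside, since the
  binarization hides Moderate/High confusions.

Undefined ratios (zero denominators) are reported as not-applicable,
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .errors import InvalidInputError
from .levels import ThreeLevelRisk

__all__ = [
    "MFS_NUMERIC",
    "POSITIVE_SET",
    "ConfusionMatrix",
    "MetricsReport",
    "mfs_to_level",
    "mfs_numeric",
    "confusion",
    "metrics",
    "compare_report",
]

#: Numeric equivalent of each MFS-derived level on the [0, 1] risk axis.
MFS_NUMERIC: dict[ThreeLevelRisk, float] = {
    ThreeLevelRisk.LOW: 0.3,
    ThreeLevelRisk.MODERATE: 0.6,
    ThreeLevelRisk.HIGH: 0.9,
}

#: Default positive ("at-risk") class for binarization.
POSITIVE_SET = frozenset({ThreeLevelRisk.MODERATE, ThreeLevelRisk.HIGH})


def mfs_to_level(score: float) -> ThreeLevelRisk:
    """Threshold an MFS total score into Low / Moderate / High.

    Both band endpoints 25 and 45 map to Moderate.
    """
    if not 0 <= score <= 125:
        raise InvalidInputError(f"MFS score must be in [0, 125], got {score}")
    if score < 25:
        return ThreeLevelRisk.LOW
    if score <= 45:
        return ThreeLevelRisk.MODERATE
    return ThreeLevelRisk.HIGH


def mfs_numeric(level: ThreeLevelRisk) -> float:
    return MFS_NUMERIC[level]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    pred: Sequence[ThreeLevelRisk],
    truth: Sequence[ThreeLevelRisk],
    positive_set: frozenset[ThreeLevelRisk] = POSITIVE_SET,
) -> ConfusionMatrix:
    """Binarized confusion matrix of predictions against ground truth."""
    if len(pred) != len(truth):
        raise InvalidInputError(
            f"prediction/truth length mismatch: {len(pred)} vs {len(truth)}"
        )
    if len(pred) == 0:
        raise InvalidInputError("cannot score an empty cohort")
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth):
        p_pos, t_pos = p in positive_set, t in positive_set
        if p_pos and t_pos:
            tp += 1
        elif not p_pos and not t_pos:
            tn += 1
        elif p_pos:
            fp += 1
        else:
            fn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _pct(numerator: int, denominator: int) -> float | None:
    """Percentage rounded half-up to two decimals; None when undefined."""
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, sensitivity, specificity as percentages (two decimals).

    A ``None`` entry means the ratio is undefined (zero denominator).
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    if cm.n < 1:
        raise InvalidInputError("confusion matrix is empty")
    return MetricsReport(
        accuracy=_pct(cm.tp + cm.tn, cm.n),
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
    )


def compare_report(
    pred: dict[str, ThreeLevelRisk],
    truth: dict[str, ThreeLevelRisk],
    positive_set: frozenset[ThreeLevelRisk] = POSITIVE_SET,
) -> dict:
    """Per-participant agreement table plus confusion matrix and metrics.

    ``pred`` and ``truth`` map participant id -> level; only ids present
    in both are scored, and an empty intersection is an error.
    """
    ids = [i for i in pred if i in truth]
    if not ids:
        raise InvalidInputError("no participant ids shared between pred and truth")
    rows = [
        {
            "id": i,
            "pred": str(pred[i]),
            "truth": str(truth[i]),
            "match": pred[i] == truth[i],
        }
        for i in ids
    ]
    mismatch_ids = [r["id"] for r in rows if not r["match"]]
    cm = confusion([pred[i] for i in ids], [truth[i] for i in ids], positive_set)
    rep = metrics(cm)
    return {
        "rows": rows,
        "mismatch_ids": mismatch_ids,
        "exact_match": (len(ids) - len(mismatch_ids)) / len(ids),
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "metrics": {
            "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
        },
        "unmatched_pred_ids": [i for i in pred if i not in truth],
        "unmatched_truth_ids": [i for i in truth if i not in pred],
    }
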