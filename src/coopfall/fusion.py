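"""Non-learning comparator strategies for combining the two model outputs.

Three strategies are provided for merging the five-level vital-sign
prediction (AI1) with the three-level ADL prediction (AI2):

* **score fusion** — each level is mapped to a numeric weight, the two
  weights are averaged, and the mean score is banded into
  Low (<= 0.40) / Moderate (<= 0.80) / High (> 0.80);
* **rule fusion** — agreement keeps the shared category, disagreement
  resolves to the higher severity on the shared scale, and Emergency
  always dominates;
* **decision-tree fusion** — an ordered rule list evaluated first-match-
  wins, optionally emitting hyphenated in-between labels
  ("Moderate–High", "Low-Moderate") for borderline combinations; pairs
  not covered by any row fall through to rule fusion.

These comparators have no trainable parameters; the learned alternative
lives in :mod:`coopfall.meta`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import InvalidInputError
from .levels import FiveLevelRisk, ThreeLevelRisk

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMap",
    "TABLE1_WEIGHTS",
    "TABLE4_WEIGHTS",
    "FusionResult",
    "score_fusion",
    "classify_score",
    "rule_fusion",
    "decision_tree_fusion",
    "project_tree_label",
]


@dataclass(frozen=True)
class WeightMap:
    """Numeric severity weights for the two level scales."""

    variant: str
    ai1_weights: dict[FiveLevelRisk, float]
    ai2_weights: dict[ThreeLevelRisk, float]

    def __post_init__(self) -> None:
        for scale in (self.ai1_weights, self.ai2_weights):
            vals = [scale[k] for k in sorted(scale)]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise InvalidInputError("weights must increase strictly with severity")
            if any(not 0 < v <= 1 for v in vals):
                raise InvalidInputError("weights must lie in (0, 1]")


_AI1_WEIGHTS = {
    FiveLevelRisk.NORMAL: 0.2,
    FiveLevelRisk.LOW: 0.4,
    FiveLevelRisk.MODERATE: 0.6,
    FiveLevelRisk.HIGH: 0.8,
    FiveLevelRisk.EMERGENCY: 1.0,
}

#: Score-fusion weights: AI2 levels at thirds of the unit scale.
TABLE1_WEIGHTS = WeightMap(
    variant="table1",
    ai1_weights=dict(_AI1_WEIGHTS),
    ai2_weights={
        ThreeLevelRisk.LOW: 0.33,
        ThreeLevelRisk.MODERATE: 0.66,
        ThreeLevelRisk.HIGH: 0.99,
    },
)

#: Meta-model weights: AI2 levels aligned with the shared AI1 values.
TABLE4_WEIGHTS = WeightMap(
    variant="table4",
    ai1_weights=dict(_AI1_WEIGHTS),
    ai2_weights={
        ThreeLevelRisk.LOW: 0.4,
        ThreeLevelRisk.MODERATE: 0.6,
        ThreeLevelRisk.HIGH: 0.8,
    },
)


@dataclass(frozen=True)
class FusionResult:
    """Outcome of one comparator: label, method tag, and (for score
    fusion only) the combined score."""

    level: str
    method: str
    s_combined: float | None = None


def classify_score(s: float) -> ThreeLevelRisk:
    """Band a combined score: Low <= 0.40 < Moderate <= 0.80 < High.

    The bands are half-open so every score in [0, 1] is classifiable
    (the printed 0.40/0.41 gap is closed; 0.405-type values are
    Moderate).
    """
    if not 0.0 <= s <= 1.0:
        raise InvalidInputError(f"combined score must be in [0, 1], got {s}")
    if s <= 0.40:
        return ThreeLevelRisk.LOW
    if s <= 0.80:
        return ThreeLevelRisk.MODERATE
    return ThreeLevelRisk.HIGH


def score_fusion(
    ai1: FiveLevelRisk,
    ai2: ThreeLevelRisk,
    weights: WeightMap = TABLE1_WEIGHTS,
) -> FusionResult:
    """Weighted-average score fusion: s = (w1 + w2) / 2, banded."""
    s = (weights.ai1_weights[ai1] + weights.ai2_weights[ai2]) / 2.0
    return FusionResult(level=str(classify_score(s)), method="score_fusion",
                        s_combined=s)


def rule_fusion(ai1: FiveLevelRisk, ai2: ThreeLevelRisk) -> FiveLevelRisk:
    """Priority rule fusion on the shared severity scale.

    Agreement keeps the category; otherwise the higher severity wins,
    so an Emergency vital-sign prediction always dominates.
    """
    return max(ai1, ai2.to_five())


#: Ordered decision-tree rows: (ai1 or None=Any, ai2 or None=Any, label,
#: weighted-variant-only flag).  First match wins.
_TREE_ROWS: list[tuple[FiveLevelRisk | None, ThreeLevelRisk | None, str, bool]] = [
    (FiveLevelRisk.EMERGENCY, None, "Emergency", False),
    (FiveLevelRisk.LOW, ThreeLevelRisk.LOW, "Low", False),
    (FiveLevelRisk.MODERATE, ThreeLevelRisk.HIGH, "Moderate-High", True),
    (FiveLevelRisk.MODERATE, ThreeLevelRisk.HIGH, "High", False),
    (FiveLevelRisk.LOW, ThreeLevelRisk.MODERATE, "Low-Moderate", True),
]


def decision_tree_fusion(
    ai1: FiveLevelRisk, ai2: ThreeLevelRisk, weighted: bool = False
) -> FusionResult:
    """Hierarchical first-match fusion with optional in-between labels.

    With ``weighted`` on, borderline pairs resolve to the hyphenated
    adaptive labels; otherwise the strict rows apply.  A pair covered by
    no row falls through to :func:`rule_fusion` (logged).
    """
    for row_ai1, row_ai2, label, weighted_only in _TREE_ROWS:
        if weighted_only and not weighted:
            continue
        if (row_ai1 is None or row_ai1 == ai1) and (row_ai2 is None or row_ai2 == ai2):
            return FusionResult(level=label, method="decision_tree")
    logger.info("pair (%s, %s) not covered by decision tree; using rule fusion",
                ai1, ai2)
    return FusionResult(level=str(rule_fusion(ai1, ai2)), method="decision_tree")


def project_tree_label(label: str) -> FiveLevelRisk:
    """Project a (possibly hyphenated) tree label onto the five-level
    scale by taking the higher-severity component.

    This is the documented evaluation projection; hyphenated labels are
    never silently coerced elsewhere.
    """
    parts = [p for p in label.replace("–", "-").split("-") if p]
    return max(FiveLevelRisk.from_name(p) for p in parts)
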