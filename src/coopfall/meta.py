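"""Cooperative meta-model: weight mapping, combined score, and a
random-forest meta-classifier stacked on the two base models.

The meta-model takes the categorical outputs of the vital-sign model
(five levels) and the ADL model (three levels), maps each to a numeric
severity weight (Normal 0.2 ... Emergency 1.0; Low 0.4 / Moderate 0.6 /
High 0.8), and computes the combined risk score

    S_combined = (W_AI1 + W_AI2) / 2

which is banded into Low (<= 0.40), Moderate (<= 0.80), High (> 0.80).
A random forest (100 trees, depth <= 10, min_samples_split 4) is
trained on the two mapped weights as the only features, with Morse Fall
Scale-derived risk levels as labels, and predicts the final level by
majority vote across trees.  Vote ties are broken toward the lower
severity and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import InvalidInputError, StateError
from .fusion import TABLE4_WEIGHTS, WeightMap, classify_score
from .levels import FiveLevelRisk, ThreeLevelRisk

logger = logging.getLogger(__name__)

__all__ = [
    "MetaConfig",
    "TrainingSet",
    "MetaPrediction",
    "MetaModel",
    "map_weights",
    "combined_score",
    "classify_combined",
    "threshold_training_set",
    "train_meta",
    "predict_meta",
]


@dataclass(frozen=True)
class MetaConfig:
    """Forest hyperparameters and the level-to-weight map."""

    n_trees: int = 100
    max_depth: int = 10
    min_samples_split: int = 4
    seed: int = 0
    weights: WeightMap = field(default_factory=lambda: TABLE4_WEIGHTS)

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.min_samples_split) < 1:
            raise InvalidInputError("forest hyperparameter counts must be >= 1")


@dataclass(frozen=True)
class TrainingSet:
    """Rows of (w_ai1, w_ai2) with MFS-derived three-level labels."""

    features: np.ndarray  # (n, 2)
    labels: tuple[ThreeLevelRisk, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] != len(self.labels):
            raise InvalidInputError(
                "training set needs an (n, 2) feature array and n labels"
            )
        object.__setattr__(self, "features", X)


@dataclass(frozen=True)
class MetaPrediction:
    """Final prediction for one participant."""

    s_combined: float
    r_pred: ThreeLevelRisk
    vote_counts: dict[ThreeLevelRisk, int]


def map_weights(
    ai1: FiveLevelRisk, ai2: ThreeLevelRisk, cfg: MetaConfig | None = None
) -> tuple[float, float]:
    """Exact table lookup of the two severity weights."""
    w = (cfg or MetaConfig()).weights
    return w.ai1_weights[ai1], w.ai2_weights[ai2]


def combined_score(w1: float, w2: float) -> float:
    """Arithmetic mean of the two mapped weights."""
    if not (0 < w1 <= 1 and 0 < w2 <= 1):
        raise InvalidInputError("weights must lie in (0, 1]")
    return (w1 + w2) / 2.0


#: Threshold banding of the combined score (shared with score fusion).
classify_combined = classify_score


def threshold_training_set(
    cfg: MetaConfig | None = None, copies: int = 2
) -> TrainingSet:
    """Training set labeled by the threshold rule itself.

    Enumerates all 15 (AI1, AI2) level pairs, ``copies`` times, labeling
    each by ``classify_combined(combined_score(...))``.  This is the
    documented fallback when MFS labels are unavailable; with copies=2
    it matches the 30-participant training-cohort size.
    """
    cfg = cfg or MetaConfig()
    rows, labels = [], []
    for _ in range(copies):
        for ai1 in FiveLevelRisk:
            for ai2 in ThreeLevelRisk:
                w1, w2 = map_weights(ai1, ai2, cfg)
                rows.append((w1, w2))
                labels.append(classify_combined(combined_score(w1, w2)))
    return TrainingSet(features=np.asarray(rows), labels=tuple(labels))


@dataclass
class MetaModel:
    """Trained forest plus its configuration."""

    forest: RandomForestClassifier
    config: MetaConfig
    training_set: TrainingSet


def train_meta(data: TrainingSet, cfg: MetaConfig | None = None) -> MetaModel:
    """Fit the random-forest meta-classifier.

    Each of the ``n_trees`` trees is grown on a full-size bootstrap
    resample, splitting on both weight features (no feature
    subsampling — there are only two).  Deterministic given the seed.
    """
    cfg = cfg or MetaConfig()
    if data.features.shape[0] < 2:
        raise InvalidInputError("meta-model training needs at least 2 samples")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        min_samples_split=cfg.min_samples_split,
        max_features=None,
        bootstrap=True,
        random_state=cfg.seed,
    )
    forest.fit(data.features, [int(l) for l in data.labels])
    return MetaModel(forest=forest, config=cfg, training_set=data)


def predict_meta(
    model: MetaModel, ai1: FiveLevelRisk, ai2: ThreeLevelRisk
) -> MetaPrediction:
    """Predict the final risk level for one participant.

    ``s_combined`` is always computed from the weight map; ``r_pred`` is
    the plurality vote of the forest's trees, ties broken toward the
    lower severity (logged).
    """
    forest = getattr(model, "forest", None)
    if forest is None or not hasattr(forest, "estimators_"):
        raise StateError("meta-model forest is not trained")
    w1, w2 = map_weights(ai1, ai2, model.config)
    s = combined_score(w1, w2)
    x = np.asarray([[w1, w2]])
    votes = dict.fromkeys(ThreeLevelRisk, 0)
    for tree in forest.estimators_:
        # estimators are fit on encoded labels: indices into forest.classes_
        cls = int(forest.classes_[int(tree.predict(x)[0])])
        votes[ThreeLevelRisk(cls)] += 1
    top = max(votes.values())
    winners = [lvl for lvl, n in votes.items() if n == top]
    if len(winners) > 1:
        logger.info("tied tree votes %s; choosing lower severity", votes)
    return MetaPrediction(s_combined=s, r_pred=min(winners), vote_counts=votes)
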