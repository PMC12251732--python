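"""Deep-belief-network fall-risk model over Activities of Daily Living.

Input is a sequence of ADL bouts (activity label + duration in seconds)
for one participant.  Each of the five activities carries a fixed
significance weight for fall prediction — sitting 0.2, standing 0.4,
walking 0.6, running 0.8, jumping 1.0 — and the feature vector is the
per-activity time fraction multiplied by that weight, so every entry
lies in [0, weight] and the vector lives in the unit hypercube.

The network is a stack of Bernoulli restricted Boltzmann machines
pretrained greedily with contrastive divergence (CD-k), topped by a
3-class softmax head and fine-tuned end to end by backpropagation with
the Adam optimizer on cross-entropy loss.  Real-valued features in
[0, 1] are treated as Bernoulli probabilities during CD.  The output is
one of three ordinal risk levels (Low, Moderate, High); prediction ties
are broken toward the lower severity and logged.

Default architecture 5 -> 16 -> 8 -> softmax(3); CD-1; 50 pretraining
epochs at learning rate 0.01; 200 fine-tuning epochs with Adam step
1e-2 and moment decay 0.9/0.999; full-batch at cohort scale.  All
hyperparameters are exposed through :class:`DBNConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, StateError
from .levels import ThreeLevelRisk

logger = logging.getLogger(__name__)

__all__ = [
    "ACTIVITIES",
    "ACTIVITY_WEIGHTS",
    "ADLBout",
    "ADLFeatureVector",
    "RBMLayer",
    "DBNConfig",
    "DBNModel",
    "build_adl_features",
    "rbm_hidden_prob",
    "rbm_visible_prob",
    "pretrain",
    "fine_tune",
    "train_ai2",
    "predict_ai2",
]

#: Closed activity vocabulary, in fixed feature order.
ACTIVITIES: tuple[str, ...] = ("sitting", "standing", "walking", "running", "jumping")

#: Fall-prediction significance weight per activity.
ACTIVITY_WEIGHTS: dict[str, float] = {
    "sitting": 0.2,
    "standing": 0.4,
    "walking": 0.6,
    "running": 0.8,
    "jumping": 1.0,
}


@dataclass(frozen=True)
class ADLBout:
    """One contiguous bout of a single activity."""

    activity: str
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise InvalidInputError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )
        if not (math.isfinite(self.duration) and self.duration >= 0):
            raise InvalidInputError(
                f"bout duration must be finite and >= 0, got {self.duration}"
            )


@dataclass(frozen=True)
class ADLFeatureVector:
    """Weighted activity-mix features for one participant."""

    weighted_fraction: tuple[float, ...]  # ordered as ACTIVITIES
    time_fraction: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weighted_fraction, dtype=float)


def build_adl_features(bouts: Iterable[ADLBout]) -> ADLFeatureVector:
    """Aggregate bouts into the weighted time-fraction feature vector."""
    totals = dict.fromkeys(ACTIVITIES, 0.0)
    grand = 0.0
    for bout in bouts:
        totals[bout.activity] += bout.duration
        grand += bout.duration
    if grand <= 0:
        raise InvalidInputError("ADL bout list is empty or has zero total duration")
    fractions = tuple(totals[a] / grand for a in ACTIVITIES)
    weighted = tuple(f * ACTIVITY_WEIGHTS[a] for f, a in zip(fractions, ACTIVITIES))
    return ADLFeatureVector(weighted_fraction=weighted, time_fraction=fractions)


# --------------------------------------------------------------------------
# Restricted Boltzmann Machine
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class RBMLayer:
    """One RBM: bipartite weights plus visible and hidden biases."""

    weights: np.ndarray       # (n_visible, n_hidden)
    visible_bias: np.ndarray  # (n_visible,)
    hidden_bias: np.ndarray   # (n_hidden,)

    def __post_init__(self) -> None:
        nv, nh = self.weights.shape
        if self.visible_bias.shape != (nv,) or self.hidden_bias.shape != (nh,):
            raise InvalidInputError("RBM bias shapes inconsistent with weights")
        if not (np.isfinite(self.weights).all()
                and np.isfinite(self.visible_bias).all()
                and np.isfinite(self.hidden_bias).all()):
            raise InvalidInputError("RBM parameters must be finite")


def rbm_hidden_prob(layer: RBMLayer, visible: np.ndarray) -> np.ndarray:
    """P(h=1 | v), elementwise logistic of hidden_bias + v.W."""
    visible = np.asarray(visible, dtype=float)
    if visible.shape[-1] != layer.weights.shape[0]:
        raise InvalidInputError(
            f"visible dimension {visible.shape[-1]} != {layer.weights.shape[0]}"
        )
    return _sigmoid(layer.hidden_bias + visible @ layer.weights)


def rbm_visible_prob(layer: RBMLayer, hidden: np.ndarray) -> np.ndarray:
    """P(v=1 | h), elementwise logistic of visible_bias + h.W^T."""
    hidden = np.asarray(hidden, dtype=float)
    if hidden.shape[-1] != layer.weights.shape[1]:
        raise InvalidInputError(
            f"hidden dimension {hidden.shape[-1]} != {layer.weights.shape[1]}"
        )
    return _sigmoid(layer.visible_bias + hidden @ layer.weights.T)


@dataclass(frozen=True)
class DBNConfig:
    """Hyperparameters of the DBN; defaults are the desk-scale settings."""

    layer_sizes: tuple[int, ...] = (5, 16, 8)
    n_classes: int = 3
    cd_k: int = 1
    pretrain_epochs: int = 50
    pretrain_lr: float = 0.01
    finetune_epochs: int = 200
    adam_lr: float = 1e-2  # 1e-3 underfits small cohorts within 200 epochs
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int | None = None  # None = full batch
    seed: int = 0


def _init_rbm(nv: int, nh: int, rng: np.random.Generator) -> RBMLayer:
    return RBMLayer(
        weights=rng.normal(0.0, 0.01, size=(nv, nh)),
        visible_bias=np.zeros(nv),
        hidden_bias=np.zeros(nh),
    )


def _cd_update(layer: RBMLayer, batch: np.ndarray, lr: float, k: int,
               rng: np.random.Generator) -> float:
    """One CD-k step on a batch; returns mean reconstruction error."""
    v0 = batch
    h0 = rbm_hidden_prob(layer, v0)
    vk, hk = v0, h0
    for _ in range(k):
        h_sample = (rng.random(hk.shape) < hk).astype(float)
        vk = rbm_visible_prob(layer, h_sample)
        hk = rbm_hidden_prob(layer, vk)
    n = batch.shape[0]
    layer.weights += lr * (v0.T @ h0 - vk.T @ hk) / n
    layer.visible_bias += lr * (v0 - vk).mean(axis=0)
    layer.hidden_bias += lr * (h0 - hk).mean(axis=0)
    return float(np.mean((v0 - vk) ** 2))


def pretrain(
    data: np.ndarray, config: DBNConfig, seed: int | None = None
) -> list[RBMLayer]:
    """Greedy layer-wise CD-k pretraining.

    Each layer is trained on the previous layer's hidden activation
    probabilities.  Returns the trained RBM stack; seeded and
    reproducible.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise InvalidInputError("pretraining needs a non-empty 2-D feature array")
    if not np.isfinite(X).all():
        raise InvalidInputError("NaN or infinite entries in pretraining data")
    if X.min() < 0 or X.max() > 1:
        raise InvalidInputError("pretraining features must be scaled to [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.layer_sizes
    layers: list[RBMLayer] = []
    inp = X
    for nv, nh in zip(sizes[:-1], sizes[1:]):
        if inp.shape[1] != nv:
            raise InvalidInputError(
                f"layer expects {nv} visible units, got {inp.shape[1]}"
            )
        layer = _init_rbm(nv, nh, rng)
        batch_size = config.batch_size or inp.shape[0]
        for _ in range(config.pretrain_epochs):
            for start in range(0, inp.shape[0], batch_size):
                _cd_update(layer, inp[start:start + batch_size],
                           config.pretrain_lr, config.cd_k, rng)
        layers.append(layer)
        inp = rbm_hidden_prob(layer, inp)
    return layers


# --------------------------------------------------------------------------
# Supervised head and fine-tuning
# --------------------------------------------------------------------------

@dataclass
class DBNModel:
    """RBM stack plus 3-class softmax head."""

    layers: list[RBMLayer]
    head_weights: np.ndarray | None = None  # (last_hidden, n_classes)
    head_bias: np.ndarray | None = None
    config: DBNConfig = field(default_factory=DBNConfig)
    trained: bool = False

    def _check_stack(self) -> None:
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if a.weights.shape[1] != b.weights.shape[0]:
                raise InvalidInputError("adjacent RBM layer sizes inconsistent")

    def forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Sigmoid pass through the stack, softmax at the head.

        Returns (per-layer activations incl. input, class probabilities).
        """
        if self.head_weights is None:
            raise StateError("model head is not initialized; train first")
        acts = [np.asarray(X, dtype=float)]
        for layer in self.layers:
            acts.append(_sigmoid(layer.hidden_bias + acts[-1] @ layer.weights))
        logits = acts[-1] @ self.head_weights + self.head_bias
        logits -= logits.max(axis=-1, keepdims=True)
        ez = np.exp(logits)
        return acts, ez / ez.sum(axis=-1, keepdims=True)


def fine_tune(
    model: DBNModel,
    features: np.ndarray,
    labels: Sequence[ThreeLevelRisk | int],
    config: DBNConfig | None = None,
    seed: int | None = None,
) -> DBNModel:
    """Backpropagation fine-tuning of the whole stack with Adam.

    Minimizes multiclass cross-entropy; deterministic given the seed.
    Returns the model (mutated in place) with ``trained=True``.
    """
    cfg = config or model.config
    X = np.asarray(features, dtype=float)
    y = np.asarray([int(l) for l in labels])
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidInputError("fine-tuning needs a non-empty 2-D feature array")
    if not np.isfinite(X).all():
        raise InvalidInputError("NaN or infinite entries in fine-tuning data")
    if X.shape[0] != y.shape[0]:
        raise InvalidInputError("feature/label row counts differ")
    model._check_stack()

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_hidden = model.layers[-1].weights.shape[1]
    if model.head_weights is None:
        model.head_weights = rng.normal(0.0, 0.01, size=(n_hidden, cfg.n_classes))
        model.head_bias = np.zeros(cfg.n_classes)

    params = []
    for layer in model.layers:
        params.extend([layer.weights, layer.hidden_bias])
    params.extend([model.head_weights, model.head_bias])
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]

    onehot = np.eye(cfg.n_classes)[y]
    n = X.shape[0]
    t = 0
    for _ in range(cfg.finetune_epochs):
        acts, probs = model.forward(X)
        delta = (probs - onehot) / n  # dL/dlogits for mean cross-entropy
        grads: list[np.ndarray] = []
        g_w = acts[-1].T @ delta
        g_b = delta.sum(axis=0)
        back = delta @ model.head_weights.T
        head_grads = [g_w, g_b]
        for li in range(len(model.layers) - 1, -1, -1):
            h = acts[li + 1]
            dpre = back * h * (1.0 - h)
            grads[:0] = [acts[li].T @ dpre, dpre.sum(axis=0)]
            back = dpre @ model.layers[li].weights.T
        grads.extend(head_grads)
        t += 1
        for p, g, mi, vi in zip(params, grads, m, v):
            mi *= cfg.adam_beta1
            mi += (1 - cfg.adam_beta1) * g
            vi *= cfg.adam_beta2
            vi += (1 - cfg.adam_beta2) * g * g
            mhat = mi / (1 - cfg.adam_beta1 ** t)
            vhat = vi / (1 - cfg.adam_beta2 ** t)
            p -= cfg.adam_lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)
    model.config = cfg
    model.trained = True
    return model


def train_ai2(
    features: np.ndarray,
    labels: Sequence[ThreeLevelRisk | int],
    config: DBNConfig | None = None,
) -> DBNModel:
    """Full pipeline: CD pretraining then supervised fine-tuning."""
    cfg = config or DBNConfig()
    layers = pretrain(np.asarray(features, dtype=float), cfg)
    model = DBNModel(layers=layers, config=cfg)
    return fine_tune(model, features, labels, cfg)


def predict_ai2(
    model: DBNModel, features: ADLFeatureVector | np.ndarray
) -> tuple[ThreeLevelRisk, np.ndarray]:
    """Predict Low/Moderate/High for one participant.

    Returns ``(level, class_probabilities)``.  Exact probability ties are
    broken toward the lower severity and logged.
    """
    if not model.trained:
        raise StateError("DBN model is not trained")
    x = features.as_array() if isinstance(features, ADLFeatureVector) else features
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _, probs = model.forward(x)
    p = probs[0]
    best = int(np.argmax(p))  # argmax returns the first = lowest severity on ties
    if np.sum(p == p[best]) > 1:
        logger.info("tied class probabilities %s; choosing lower severity", p)
    return ThreeLevelRisk(best), p
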