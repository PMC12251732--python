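"""File formats and model serialization.

Tabular exchange is CSV with declared headers; predictions, reports and
model artifacts are JSON.  Risk levels are always serialized as their
canonical strings (``Normal``/``Low``/``Moderate``/``High``/
``Emergency``), never as numeric codes, because several weight maps
assign different numbers to the same level.

Model artifacts are versioned JSON.  Rule bases and DBN parameters are
stored verbatim (read ∘ write is identity to full precision).  The
random-forest artifact stores the training set, configuration and seed
and refits on load — training is deterministic given the seed, so the
reloaded forest makes identical predictions.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cohort import SimulatedParticipant
from .dbn import ADLBout, DBNConfig, DBNModel, RBMLayer
from .errors import (
    IncompatibleArtifactError,
    InvalidInputError,
)
from .fuzzy import FuzzyRuleBase, VitalSignSample, parse_rules
from .levels import FiveLevelRisk, ThreeLevelRisk
from .meta import MetaConfig, MetaModel, TrainingSet, train_meta
from .fusion import TABLE1_WEIGHTS, TABLE4_WEIGHTS, WeightMap

FORMAT_VERSION = 1

VITALS_HEADER = ["participant_id", "systolic_bp", "diastolic_bp", "heart_rate", "spo2"]
ADL_HEADER = ["participant_id", "activity", "duration_s"]
LEVELS_HEADER = ["participant_id", "ai1_level", "ai2_level"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {missing}")


def read_vitals(path: str | Path) -> list[tuple[str, VitalSignSample]]:
    """Read a vital-sign cohort CSV; pulse pressure is derived.

    Malformed rows raise errors naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, VITALS_HEADER, path)
    if df.empty:
        import logging
        logging.getLogger(__name__).warning("%s: empty cohort file", path)
    out = []
    for idx, row in df.iterrows():
        try:
            sample = VitalSignSample(
                systolic_bp=float(row.systolic_bp),
                diastolic_bp=float(row.diastolic_bp),
                heart_rate=float(row.heart_rate),
                spo2=float(row.spo2),
            )
        except (InvalidInputError, ValueError) as exc:
            raise InvalidInputError(f"{path}: row {idx + 2}: {exc}") from exc
        out.append((str(row.participant_id), sample))
    return out


def read_adl(path: str | Path) -> dict[str, list[ADLBout]]:
    """Read an ADL bout CSV grouped by participant."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ADL_HEADER, path)
    out: dict[str, list[ADLBout]] = {}
    for idx, row in df.iterrows():
        try:
            bout = ADLBout(activity=str(row.activity), duration=float(row.duration_s))
        except (InvalidInputError, ValueError) as exc:
            raise InvalidInputError(f"{path}: row {idx + 2}: {exc}") from exc
        out.setdefault(str(row.participant_id), []).append(bout)
    return out


def read_levels(path: str | Path) -> pd.DataFrame:
    """Read a per-participant level CSV (AI1/AI2 outputs, optional MFS).

    Level strings are validated; invalid rows raise with their row number.
    """
    df = pd.read_csv(path)
    _require_columns(df, LEVELS_HEADER, path)
    for idx, row in df.iterrows():
        try:
            FiveLevelRisk.from_name(str(row.ai1_level))
            ThreeLevelRisk.from_name(str(row.ai2_level))
        except InvalidInputError as exc:
            raise InvalidInputError(f"{path}: row {idx + 2}: {exc}") from exc
    return df


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: str | Path, payload: dict) -> None:
    _atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# Model artifacts
# --------------------------------------------------------------------------

def _weightmap_to_json(w: WeightMap) -> dict:
    return {
        "variant": w.variant,
        "ai1": {str(k): v for k, v in w.ai1_weights.items()},
        "ai2": {str(k): v for k, v in w.ai2_weights.items()},
    }


def _weightmap_from_json(d: dict) -> WeightMap:
    return WeightMap(
        variant=d["variant"],
        ai1_weights={FiveLevelRisk.from_name(k): v for k, v in d["ai1"].items()},
        ai2_weights={ThreeLevelRisk.from_name(k): v for k, v in d["ai2"].items()},
    )


def write_model(path: str | Path, model: Any) -> None:
    """Serialize a rule base, DBN, or meta-model forest to versioned JSON."""
    if isinstance(model, FuzzyRuleBase):
        payload = {
            "format_version": FORMAT_VERSION,
            "kind": "fuzzy_rule_base",
            "rules": [
                "IF "
                + " AND ".join(f"{v} IS {t}" for v, t in r.antecedent.items())
                + f" THEN risk IS {r.consequent}"
                for r in model.rules
            ],
        }
    elif isinstance(model, DBNModel):
        payload = {
            "format_version": FORMAT_VERSION,
            "kind": "dbn",
            "trained": model.trained,
            "config": dataclasses.asdict(model.config),
            "layers": [
                {
                    "weights": layer.weights.tolist(),
                    "visible_bias": layer.visible_bias.tolist(),
                    "hidden_bias": layer.hidden_bias.tolist(),
                }
                for layer in model.layers
            ],
            "head_weights": None if model.head_weights is None
            else model.head_weights.tolist(),
            "head_bias": None if model.head_bias is None
            else model.head_bias.tolist(),
        }
    elif isinstance(model, MetaModel):
        payload = {
            "format_version": FORMAT_VERSION,
            "kind": "meta_forest",
            "config": {
                "n_trees": model.config.n_trees,
                "max_depth": model.config.max_depth,
                "min_samples_split": model.config.min_samples_split,
                "seed": model.config.seed,
                "weights": _weightmap_to_json(model.config.weights),
            },
            "training": {
                "features": model.training_set.features.tolist(),
                "labels": [str(l) for l in model.training_set.labels],
            },
        }
    else:
        raise InvalidInputError(f"cannot serialize model of type {type(model)!r}")
    write_json(path, payload)


def read_model(path: str | Path) -> Any:
    """Load a versioned model artifact; inverse of :func:`write_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InvalidInputError(f"{path}: corrupted model artifact: {exc}") from exc
    version = payload.get("format_version")
    if version is None:
        raise IncompatibleArtifactError(f"{path}: missing format_version field")
    if version != FORMAT_VERSION:
        raise IncompatibleArtifactError(
            f"{path}: artifact version {version} unsupported (expected "
            f"{FORMAT_VERSION})"
        )
    kind = payload.get("kind")
    if kind == "fuzzy_rule_base":
        return parse_rules(payload["rules"], source=str(path))
    if kind == "dbn":
        cfg_d = dict(payload["config"])
        cfg_d["layer_sizes"] = tuple(cfg_d["layer_sizes"])
        model = DBNModel(
            layers=[
                RBMLayer(
                    weights=np.asarray(l["weights"]),
                    visible_bias=np.asarray(l["visible_bias"]),
                    hidden_bias=np.asarray(l["hidden_bias"]),
                )
                for l in payload["layers"]
            ],
            head_weights=None if payload["head_weights"] is None
            else np.asarray(payload["head_weights"]),
            head_bias=None if payload["head_bias"] is None
            else np.asarray(payload["head_bias"]),
            config=DBNConfig(**cfg_d),
            trained=bool(payload["trained"]),
        )
        return model
    if kind == "meta_forest":
        cfg_d = payload["config"]
        cfg = MetaConfig(
            n_trees=cfg_d["n_trees"],
            max_depth=cfg_d["max_depth"],
            min_samples_split=cfg_d["min_samples_split"],
            seed=cfg_d["seed"],
            weights=_weightmap_from_json(cfg_d["weights"]),
        )
        data = TrainingSet(
            features=np.asarray(payload["training"]["features"]),
            labels=tuple(
                ThreeLevelRisk.from_name(l) for l in payload["training"]["labels"]
            ),
        )
        # deterministic refit: identical forest, identical predictions
        return train_meta(data, cfg)
    raise IncompatibleArtifactError(f"{path}: unknown artifact kind {kind!r}")


# --------------------------------------------------------------------------
# Cohort frames (simulate output)
# --------------------------------------------------------------------------

def vitals_frame(cohort: list[SimulatedParticipant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": p.id,
                "systolic_bp": p.vitals.systolic_bp,
                "diastolic_bp": p.vitals.diastolic_bp,
                "heart_rate": p.vitals.heart_rate,
                "spo2": p.vitals.spo2,
            }
            for p in cohort
        ],
        columns=VITALS_HEADER,
    )


def adl_frame(cohort: list[SimulatedParticipant]) -> pd.DataFrame:
    rows = [
        {"participant_id": p.id, "activity": b.activity, "duration_s": b.duration}
        for p in cohort
        for b in p.bouts
    ]
    return pd.DataFrame(rows, columns=ADL_HEADER)


def merged_frame(cohort: list[SimulatedParticipant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": p.id,
                "age": p.age,
                "fall_history": p.fall_history,
                "latent": p.latent,
                "mfs_score": p.mfs_score,
                "mfs_level": str(p.mfs_level),
            }
            for p in cohort
        ]
    )


def weight_map_by_name(name: str) -> WeightMap:
    try:
        return {"table1": TABLE1_WEIGHTS, "table4": TABLE4_WEIGHTS}[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown weight-map variant {name!r}; expected table1 or table4"
        ) from None
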