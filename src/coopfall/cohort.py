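"""Synthetic cohort generators, indirect pairing, and the embedded
10-participant comparison fixture.

The package's source setting has no public dataset that carries vital
signs and Activities of Daily Living for the *same* older adults, so
two things stand in:

* risk-conditioned simulators (:func:`generate_vitals`,
  :func:`generate_adl`, :func:`simulate_cohort`) drawing from the
  synthetic profiles in ``data/profiles.yaml`` — truncated-normal vital
  signs (low-risk centered at normotensive/normoxic values, high-risk
  at hypotensive/tachycardic/desaturated ones) and multinomial
  activity-bout sequences;
* **indirect pairing** (:func:`indirect_pairing`): one vital-sign
  participant and one ADL participant with equal age, equal fall-history
  count (optionally ±1) and the same MFS level are merged into a single
  evaluation record.

:func:`table5_fixture` embeds the 10 merged test participants of the
published comparison (fall history, AI1/AI2 inputs, printed meta-model
and MFS prediction columns).  The fixture's ages are synthetic
placeholders: the printed table carries no ages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import stats

from .dbn import ACTIVITIES, ADLBout
from .errors import ConfigurationError, InvalidInputError
from .fuzzy import VitalSignSample
from .levels import FiveLevelRisk, ThreeLevelRisk

logger = logging.getLogger(__name__)

__all__ = [
    "RiskProfile",
    "load_profiles",
    "default_profiles",
    "MergedParticipant",
    "CohortEntry",
    "PairingResult",
    "SimulatedParticipant",
    "generate_vitals",
    "generate_adl",
    "generate_mfs_score",
    "simulate_cohort",
    "indirect_pairing",
    "table5_fixture",
    "Table5Fixture",
]


@dataclass(frozen=True)
class RiskProfile:
    """Generative parameters of one latent risk class."""

    label: str
    vital_distributions: dict[str, dict[str, float]]
    adl_mix: dict[str, float]
    mfs_range: tuple[int, int]
    fall_rate: float

    def __post_init__(self) -> None:
        needed = {"diastolic_bp", "pulse_pressure", "heart_rate", "spo2"}
        if set(self.vital_distributions) != needed:
            raise ConfigurationError(
                f"profile {self.label!r} must parameterize exactly {sorted(needed)}"
            )
        if set(self.adl_mix) - set(ACTIVITIES):
            raise ConfigurationError(
                f"profile {self.label!r} has unknown activities in adl_mix"
            )
        if abs(sum(self.adl_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"profile {self.label!r}: adl_mix must sum to 1"
            )

    @property
    def level(self) -> ThreeLevelRisk:
        return ThreeLevelRisk.from_name(self.label)


def load_profiles(text: str) -> dict[str, RiskProfile]:
    raw = yaml.safe_load(text)
    profiles = {}
    for label, spec in raw.items():
        profiles[label] = RiskProfile(
            label=label,
            vital_distributions=spec["vitals"],
            adl_mix={a: float(spec["adl_mix"].get(a, 0.0)) for a in ACTIVITIES},
            mfs_range=tuple(spec["mfs_range"]),
            fall_rate=float(spec["fall_rate"]),
        )
    return profiles


def default_profiles() -> dict[str, RiskProfile]:
    text = resources.files("coopfall.data").joinpath("profiles.yaml").read_text()
    return load_profiles(text)


def _truncnorm(rng: np.random.Generator, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_vitals(
    profile: RiskProfile, n: int, seed: int | np.random.Generator = 0
) -> list[VitalSignSample]:
    """Draw ``n`` vital-sign samples from the profile's truncated normals.

    Systolic pressure is diastolic + pulse pressure, so every sample
    satisfies the systolic > diastolic > 0 invariant by construction.
    """
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    d = profile.vital_distributions

    def draw(sign):
        p = d[sign]
        return _truncnorm(rng, p["mean"], p["sd"], p["low"], p["high"], n)

    dia, pp, hr, spo2 = draw("diastolic_bp"), draw("pulse_pressure"), \
        draw("heart_rate"), draw("spo2")
    return [
        VitalSignSample(
            systolic_bp=float(dia[i] + pp[i]),
            diastolic_bp=float(dia[i]),
            heart_rate=float(hr[i]),
            spo2=float(min(spo2[i], 100.0)),
        )
        for i in range(n)
    ]


def generate_adl(
    profile: RiskProfile,
    total_duration: float,
    seed: int | np.random.Generator = 0,
    mean_bout_s: float = 60.0,
) -> list[ADLBout]:
    """Draw an activity-bout sequence totalling ``total_duration`` seconds.

    Activities are sampled i.i.d. from the profile mix; bout lengths
    from a gamma distribution (shape 4) with the given mean, final bout
    truncated so the total is conserved exactly.
    """
    if total_duration <= 0:
        raise InvalidInputError("total_duration must be > 0")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    probs = np.asarray([profile.adl_mix[a] for a in ACTIVITIES])
    durations = np.empty(0)
    while durations.sum() < total_duration:
        chunk = max(16, int((total_duration - durations.sum()) / mean_bout_s * 1.5))
        durations = np.concatenate(
            [durations, rng.gamma(4.0, mean_bout_s / 4.0, size=chunk)]
        )
    cut = int(np.searchsorted(np.cumsum(durations), total_duration)) + 1
    durations = durations[:cut]
    # truncate the final bout so the total is conserved exactly
    durations[-1] -= durations.sum() - total_duration
    acts = rng.choice(len(ACTIVITIES), size=cut, p=probs)
    return [
        ADLBout(activity=ACTIVITIES[a], duration=float(d))
        for a, d in zip(acts, durations)
    ]


def generate_mfs_score(
    profile: RiskProfile, seed: int | np.random.Generator = 0
) -> int:
    """Uniform integer MFS score within the latent class's band."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    lo, hi = profile.mfs_range
    return int(rng.integers(lo, hi + 1))


@dataclass(frozen=True)
class MergedParticipant:
    """One paired evaluation record (vital-sign + ADL participant)."""

    id: str
    age: int
    fall_history: int
    ai1_level: FiveLevelRisk
    ai2_level: ThreeLevelRisk
    mfs_level: ThreeLevelRisk

    def __post_init__(self) -> None:
        if self.age < 60:
            raise InvalidInputError("cohort covers adults aged 60 and older")
        if self.fall_history < 0:
            raise InvalidInputError("fall history count must be >= 0")


@dataclass(frozen=True)
class CohortEntry:
    """One single-modality participant offered to the pairing step."""

    id: str
    age: int
    fall_history: int
    mfs_level: ThreeLevelRisk
    level: FiveLevelRisk | ThreeLevelRisk  # the modality model's prediction


@dataclass(frozen=True)
class PairingResult:
    merged: list[MergedParticipant]
    unmatched_ai1: list[str]
    unmatched_ai2: list[str]


def indirect_pairing(
    ai1_cohort: list[CohortEntry],
    ai2_cohort: list[CohortEntry],
    fall_history_tolerance: int = 0,
) -> PairingResult:
    """Greedy one-to-one merge of a vital-sign cohort with an ADL cohort.

    Participants are matched on exact age equality, fall-history count
    equality within ``fall_history_tolerance`` (0 = exact, 1 = ±1), and
    identical MFS level.  Each participant is used at most once;
    unmatched ids are reported.  No match at all yields an empty result
    with a warning, not an error.
    """
    if not ai1_cohort or not ai2_cohort:
        raise InvalidInputError("both cohorts must be non-empty")
    used: set[str] = set()
    merged: list[MergedParticipant] = []
    for a in ai1_cohort:
        mate = next(
            (
                b for b in ai2_cohort
                if b.id not in used
                and b.age == a.age
                and abs(b.fall_history - a.fall_history) <= fall_history_tolerance
                and b.mfs_level == a.mfs_level
            ),
            None,
        )
        if mate is None:
            continue
        used.add(mate.id)
        merged.append(
            MergedParticipant(
                id=f"{a.id}+{mate.id}",
                age=a.age,
                fall_history=a.fall_history,
                ai1_level=FiveLevelRisk(a.level) if not isinstance(
                    a.level, ThreeLevelRisk) else a.level.to_five(),
                ai2_level=ThreeLevelRisk(mate.level),
                mfs_level=a.mfs_level,
            )
        )
    matched_a = {m.id.split("+", 1)[0] for m in merged}
    unmatched_a = [a.id for a in ai1_cohort if a.id not in matched_a]
    unmatched_b = [b.id for b in ai2_cohort if b.id not in used]
    if not merged:
        logger.warning("indirect pairing produced no matches")
    elif unmatched_a or unmatched_b:
        logger.info("unmatched participants: AI1 %s, AI2 %s",
                    unmatched_a, unmatched_b)
    return PairingResult(merged=merged, unmatched_ai1=unmatched_a,
                         unmatched_ai2=unmatched_b)


@dataclass(frozen=True)
class SimulatedParticipant:
    """Fully simulated participant with both modalities and ground truth."""

    id: str
    age: int
    fall_history: int
    latent: str  # latent risk class label
    vitals: VitalSignSample
    bouts: tuple[ADLBout, ...]
    mfs_score: int
    mfs_level: ThreeLevelRisk


def simulate_cohort(
    n: int,
    mix: tuple[float, float, float] = (0.4, 0.35, 0.25),
    seed: int = 0,
    profiles: dict[str, RiskProfile] | None = None,
    adl_duration_s: float = 270_000.0,
) -> list[SimulatedParticipant]:
    """Simulate ``n`` participants with latent class mix (low, mod, high).

    Each participant carries one vital-sign sample, a 75-hour ADL bout
    record (the three-day continuous-monitoring horizon of long-term
    movement studies), a fall-history count (Poisson at the class rate),
    and an MFS score drawn within the class band.  Fully determined by
    the seed.
    """
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
        raise InvalidInputError("mix must be a 3-probability vector summing to 1")
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    labels = [("low", "moderate", "high")[int(k)]
              for k in rng.choice(3, size=n, p=list(mix))]
    out: list[SimulatedParticipant] = []
    for i, label in enumerate(labels):
        prof = profiles[label]
        vit = generate_vitals(prof, 1, rng)[0]
        bouts = tuple(generate_adl(prof, adl_duration_s, rng))
        mfs = generate_mfs_score(prof, rng)
        out.append(
            SimulatedParticipant(
                id=f"S{i + 1}",
                age=int(rng.integers(60, 91)),
                fall_history=int(rng.poisson(prof.fall_rate)),
                latent=label,
                vitals=vit,
                bouts=bouts,
                mfs_score=mfs,
                mfs_level=prof.level,
            )
        )
    return out


# --------------------------------------------------------------------------
# Embedded published comparison fixture
# --------------------------------------------------------------------------

_F = FiveLevelRisk
_T = ThreeLevelRisk

# id, fall_history, ai1, ai2, printed meta prediction, MFS prediction
_TABLE5_ROWS = [
    ("P1", 2, _F.MODERATE, _T.LOW, _T.MODERATE, _T.MODERATE),
    ("P2", 2, _F.MODERATE, _T.LOW, _T.MODERATE, _T.MODERATE),
    ("P3", 0, _F.MODERATE, _T.LOW, _T.MODERATE, _T.LOW),
    ("P4", 5, _F.MODERATE, _T.MODERATE, _T.MODERATE, _T.HIGH),
    ("P5", 0, _F.NORMAL, _T.LOW, _T.LOW, _T.LOW),
    ("P6", 6, _F.HIGH, _T.MODERATE, _T.MODERATE, _T.MODERATE),
    ("P7", 2, _F.HIGH, _T.LOW, _T.MODERATE, _T.MODERATE),
    ("P8", 1, _F.LOW, _T.LOW, _T.LOW, _T.MODERATE),
    ("P9", 0, _F.LOW, _T.LOW, _T.LOW, _T.LOW),
    ("P10", 2, _F.MODERATE, _T.MODERATE, _T.MODERATE, _T.MODERATE),
]


@dataclass(frozen=True)
class Table5Fixture:
    participants: list[MergedParticipant]
    meta_printed: dict[str, ThreeLevelRisk]
    mfs: dict[str, ThreeLevelRisk]


def table5_fixture() -> Table5Fixture:
    """The 10 published merged test participants.

    Returns the merged records plus the printed meta-model and MFS
    prediction columns.  Ages are synthetic placeholders (60 + row
    index): the published table does not print ages.
    """
    participants = [
        MergedParticipant(
            id=pid,
            age=60 + i,
            fall_history=fh,
            ai1_level=ai1,
            ai2_level=ai2,
            mfs_level=mfs,
        )
        for i, (pid, fh, ai1, ai2, _, mfs) in enumerate(_TABLE5_ROWS)
    ]
    return Table5Fixture(
        participants=participants,
        meta_printed={pid: meta for pid, _, _, _, meta, _ in _TABLE5_ROWS},
        mfs={pid: mfs for pid, _, _, _, _, mfs in _TABLE5_ROWS},
    )
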