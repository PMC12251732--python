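"""Mamdani fuzzy-logic fall-risk model over vital signs.

The model reads one vital-sign sample (blood pressure, pulse pressure,
heart rate, SpO2), fuzzifies each measurement through piecewise-linear
(trapezoidal) membership functions, fires a rule base of
``IF var IS term AND ... THEN risk IS level`` rules with min-AND /
max-aggregation, and defuzzifies the aggregated output set by centroid
on a [0, 1] crisp severity axis.  The crisp score is mapped to one of
five ordinal categories (Normal, Low, Moderate, High, Emergency) whose
bands partition [0, 1] at the midpoints between the five equal-width
output term centers (0.1, 0.3, 0.5, 0.7, 0.9).

The shipped default rule base (111 rules, ``data/default_rules.txt``)
is constructed from standard clinical bands — e.g. SpO2 >= 95 normal /
90–94 low / < 90 critical, hypo-/normo-/hyper-tensive systolic bands,
brady-/normo-/tachy-cardic heart-rate bands — and can be replaced by
any file in the same one-rule-per-line format.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, InvalidInputError, NoRuleFiredError
from .levels import FiveLevelRisk

__all__ = [
    "VitalSignSample",
    "MembershipFunction",
    "FuzzyRuleBase",
    "FuzzyRule",
    "DEFAULT_VARIABLES",
    "fuzzify",
    "infer",
    "predict_ai1",
    "load_rule_base",
    "default_rule_base",
]


@dataclass(frozen=True)
class VitalSignSample:
    """One vital-sign measurement set for a participant.

    Pulse pressure is systolic minus diastolic pressure; if not given it
    is derived.  All invariants are enforced at construction: a missing
    or inconsistent vital sign is a hard error, never imputed.
    """

    systolic_bp: float
    diastolic_bp: float
    heart_rate: float
    spo2: float
    pulse_pressure: float | None = None

    def __post_init__(self) -> None:
        vals = [self.systolic_bp, self.diastolic_bp, self.heart_rate, self.spo2]
        if any(v is None or not math.isfinite(v) for v in vals):
            raise InvalidInputError("vital signs must be finite numbers")
        if not self.systolic_bp > self.diastolic_bp > 0:
            raise InvalidInputError(
                f"require systolic > diastolic > 0, got "
                f"{self.systolic_bp}/{self.diastolic_bp}"
            )
        if not 0 < self.spo2 <= 100:
            raise InvalidInputError(f"SpO2 must be in (0, 100], got {self.spo2}")
        if not self.heart_rate > 0:
            raise InvalidInputError(f"heart rate must be > 0, got {self.heart_rate}")
        pp = self.systolic_bp - self.diastolic_bp
        if self.pulse_pressure is None:
            object.__setattr__(self, "pulse_pressure", pp)
        elif not math.isclose(self.pulse_pressure, pp, abs_tol=1e-9):
            raise InvalidInputError(
                f"pulse pressure {self.pulse_pressure} != systolic - diastolic {pp}"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "systolic_bp": self.systolic_bp,
            "diastolic_bp": self.diastolic_bp,
            "pulse_pressure": float(self.pulse_pressure),
            "heart_rate": self.heart_rate,
            "spo2": self.spo2,
        }


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoidal membership function on a declared universe interval.

    ``points = (a, b, c, d)`` with a <= b <= c <= d: membership rises
    linearly on [a, b], is 1 on [b, c], falls on [c, d], and is 0
    outside [a, d].  A triangle is the degenerate case b == c.
    """

    variable: str
    term: str
    points: tuple[float, float, float, float]
    universe: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        a, b, c, d = self.points
        if not (a <= b <= c <= d):
            raise ConfigurationError(
                f"membership breakpoints must be non-decreasing: {self.points}"
            )

    def degree(self, value: float) -> float:
        a, b, c, d = self.points
        if value <= a or value >= d:
            # closed plateau edges: degree 1 survives at b==a or c==d shoulders
            if b <= value <= c:
                return 1.0
            return 0.0
        if value < b:
            return (value - a) / (b - a)
        if value <= c:
            return 1.0
        return (d - value) / (d - c)

    def sampled(self, xs: np.ndarray) -> np.ndarray:
        # drop zero-length segments: np.interp misreads duplicate
        # breakpoints at shoulder ends (degree 0 instead of 1 at x == d)
        a, b, c, d = self.points
        xp, fp = [b], [1.0]
        if a < b:
            xp, fp = [a] + xp, [0.0] + fp
        if c > b:
            xp, fp = xp + [c], fp + [1.0]
        if d > c:
            xp, fp = xp + [d], fp + [0.0]
        return np.interp(xs, xp, fp, left=0.0, right=0.0)


def _trap(var: str, term: str, pts, lo: float, hi: float) -> MembershipFunction:
    return MembershipFunction(var, term, tuple(float(p) for p in pts), (lo, hi))


#: Default input membership functions, keyed by variable then term.
#: Breakpoints follow conventional adult clinical bands.
DEFAULT_VARIABLES: dict[str, dict[str, MembershipFunction]] = {
    "systolic_bp": {
        "hypotensive": _trap("systolic_bp", "hypotensive", (0, 0, 90, 100), 0, 250),
        "normotensive": _trap("systolic_bp", "normotensive", (90, 100, 130, 140), 0, 250),
        "hypertensive": _trap("systolic_bp", "hypertensive", (130, 140, 250, 250), 0, 250),
    },
    "diastolic_bp": {
        "low": _trap("diastolic_bp", "low", (0, 0, 55, 65), 0, 150),
        "normal": _trap("diastolic_bp", "normal", (55, 65, 85, 95), 0, 150),
        "high": _trap("diastolic_bp", "high", (85, 95, 150, 150), 0, 150),
    },
    "pulse_pressure": {
        "narrow": _trap("pulse_pressure", "narrow", (0, 0, 25, 35), 0, 150),
        "normal": _trap("pulse_pressure", "normal", (25, 35, 55, 65), 0, 150),
        "wide": _trap("pulse_pressure", "wide", (55, 65, 150, 150), 0, 150),
    },
    "heart_rate": {
        "bradycardic": _trap("heart_rate", "bradycardic", (0, 0, 50, 60), 0, 220),
        "normal": _trap("heart_rate", "normal", (50, 60, 95, 105), 0, 220),
        "tachycardic": _trap("heart_rate", "tachycardic", (95, 105, 220, 220), 0, 220),
    },
    "spo2": {
        "critical": _trap("spo2", "critical", (0, 0, 88, 90), 0, 100),
        "low": _trap("spo2", "low", (88, 90, 94, 96), 0, 100),
        "normal": _trap("spo2", "normal", (94, 96, 100, 100), 0, 100),
    },
}

#: Output term centers on the crisp [0, 1] severity axis, in severity order.
OUTPUT_CENTERS: dict[FiveLevelRisk, float] = {
    FiveLevelRisk.NORMAL: 0.1,
    FiveLevelRisk.LOW: 0.3,
    FiveLevelRisk.MODERATE: 0.5,
    FiveLevelRisk.HIGH: 0.7,
    FiveLevelRisk.EMERGENCY: 0.9,
}

#: Output membership functions: shoulder trapezoids at the ends,
#: triangles between, peaks at the five equal-width term centers.
OUTPUT_TERMS: dict[FiveLevelRisk, MembershipFunction] = {
    FiveLevelRisk.NORMAL: _trap("risk", "Normal", (0.0, 0.0, 0.1, 0.3), 0, 1),
    FiveLevelRisk.LOW: _trap("risk", "Low", (0.1, 0.3, 0.3, 0.5), 0, 1),
    FiveLevelRisk.MODERATE: _trap("risk", "Moderate", (0.3, 0.5, 0.5, 0.7), 0, 1),
    FiveLevelRisk.HIGH: _trap("risk", "High", (0.5, 0.7, 0.7, 0.9), 0, 1),
    FiveLevelRisk.EMERGENCY: _trap("risk", "Emergency", (0.7, 0.9, 1.0, 1.0), 0, 1),
}

#: Crisp-score band edges at midpoints between adjacent term centers.
BAND_EDGES = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class FuzzyRule:
    """One conjunctive rule: antecedent term per variable -> consequent level."""

    antecedent: Mapping[str, str]
    consequent: FiveLevelRisk


@dataclass
class FuzzyRuleBase:
    """A validated list of rules plus the identifier of their source file."""

    rules: list[FuzzyRule]
    source: str = "<memory>"
    variables: dict[str, dict[str, MembershipFunction]] = field(
        default_factory=lambda: DEFAULT_VARIABLES
    )

    def __post_init__(self) -> None:
        for i, rule in enumerate(self.rules):
            for var, term in rule.antecedent.items():
                if var not in self.variables:
                    raise ConfigurationError(
                        f"rule {i + 1} references undeclared variable {var!r}"
                    )
                if term not in self.variables[var]:
                    raise ConfigurationError(
                        f"rule {i + 1} references undeclared term "
                        f"{term!r} of variable {var!r}"
                    )

    def __len__(self) -> int:
        return len(self.rules)


_RULE_RE = re.compile(r"^IF\s+(.+?)\s+THEN\s+risk\s+IS\s+(\w+)\s*$", re.IGNORECASE)
_CLAUSE_RE = re.compile(r"^(\w+)\s+IS\s+(\w+)$", re.IGNORECASE)


def parse_rules(lines: Iterable[str], source: str = "<memory>") -> FuzzyRuleBase:
    """Parse ``IF var IS term AND ... THEN risk IS level`` lines.

    Blank lines and ``#`` comments are ignored.
    """
    rules: list[FuzzyRule] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ConfigurationError(f"{source}:{lineno}: unparsable rule: {line!r}")
        antecedent: dict[str, str] = {}
        for clause in re.split(r"\s+AND\s+", m.group(1), flags=re.IGNORECASE):
            cm = _CLAUSE_RE.match(clause.strip())
            if not cm:
                raise ConfigurationError(
                    f"{source}:{lineno}: unparsable clause: {clause!r}"
                )
            var = cm.group(1).lower()
            if var in antecedent:
                raise ConfigurationError(
                    f"{source}:{lineno}: variable {var!r} repeated in antecedent"
                )
            antecedent[var] = cm.group(2).lower()
        rules.append(FuzzyRule(antecedent, FiveLevelRisk.from_name(m.group(2))))
    return FuzzyRuleBase(rules, source=source)


def load_rule_base(path: str | Path) -> FuzzyRuleBase:
    path = Path(path)
    return parse_rules(path.read_text().splitlines(), source=str(path))


def default_rule_base() -> FuzzyRuleBase:
    """Load the shipped 111-rule default base."""
    text = resources.files("coopfall.data").joinpath("default_rules.txt").read_text()
    return parse_rules(text.splitlines(), source="coopfall:data/default_rules.txt")


def fuzzify(value: float, mfs: Mapping[str, MembershipFunction]) -> dict[str, float]:
    """Membership degree of ``value`` in each declared term of one variable."""
    if value is None or not math.isfinite(value):
        raise InvalidInputError(f"cannot fuzzify non-finite value {value!r}")
    if not mfs:
        raise ConfigurationError("no membership functions declared for variable")
    return {term: mf.degree(value) for term, mf in mfs.items()}


def infer(sample: VitalSignSample, base: FuzzyRuleBase) -> dict[FiveLevelRisk, float]:
    """Mamdani inference: per-output-term activation = max over rules of
    min over antecedent degrees."""
    if not base.rules:
        raise ConfigurationError("empty rule base")
    values = sample.as_dict()
    degrees = {
        var: fuzzify(values[var], mfs) for var, mfs in base.variables.items()
    }
    activations = {level: 0.0 for level in FiveLevelRisk}
    for rule in base.rules:
        strength = min(degrees[var][term] for var, term in rule.antecedent.items())
        if strength > activations[rule.consequent]:
            activations[rule.consequent] = strength
    return activations


def _centroid(activations: Mapping[FiveLevelRisk, float], n_grid: int = 1001) -> float:
    xs = np.linspace(0.0, 1.0, n_grid)
    agg = np.zeros_like(xs)
    for level, act in activations.items():
        if act > 0:
            np.maximum(agg, np.minimum(act, OUTPUT_TERMS[level].sampled(xs)), out=agg)
    total = np.trapezoid(agg, xs)
    if total <= 0:
        raise NoRuleFiredError("all rule activations are zero")
    return float(np.trapezoid(agg * xs, xs) / total)


def score_to_level(score: float) -> FiveLevelRisk:
    """Map a crisp [0, 1] severity score to its ordinal band."""
    for level, edge in zip(FiveLevelRisk, BAND_EDGES):
        if score <= edge:
            return level
    return FiveLevelRisk.EMERGENCY


def predict_ai1(
    sample: VitalSignSample, base: FuzzyRuleBase | None = None
) -> tuple[FiveLevelRisk, float]:
    """Predict the five-level fall risk for one vital-sign sample.

    Returns ``(level, crisp_score)`` where the crisp score is the
    centroid of the aggregated output set on [0, 1].  Raises
    :class:`NoRuleFiredError` when no rule fires at all.
    """
    if base is None:
        base = default_rule_base()
    score = _centroid(infer(sample, base))
    return score_to_level(score), score
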