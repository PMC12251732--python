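import numpy as np
import pytest

from coopfall import fuzzy
from coopfall.cohort import default_profiles, table5_fixture


@pytest.fixture(scope="session")
def rule_base():
    return fuzzy.default_rule_base()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def table5():
    return table5_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250921)


def trapezoid_degree(points, x):
    """Independent piecewise-linear membership oracle (hand arithmetic)."""
    a, b, c, d = points
    if b <= x <= c:
        return 1.0
    if a < x < b:
        return (x - a) / (b - a)
    if c < x < d:
        return (d - x) / (d - c)
    return 0.0


def brute_force_activations(sample, base):
    """Per-rule loop oracle for Mamdani activations, independent of the
    engine: recomputes every degree with :func:`trapezoid_degree` and
    takes min within, max across, rules."""
    values = sample.as_dict()
    out = {}
    for rule in base.rules:
        strength = min(
            trapezoid_degree(base.variables[var][term].points, values[var])
            for var, term in rule.antecedent.items()
        )
        out[rule.consequent] = max(out.get(rule.consequent, 0.0), strength)
    for level in fuzzy.FiveLevelRisk:
        out.setdefault(level, 0.0)
    return out


def random_sample(rng):
    """A random but invariant-respecting vital-sign sample."""
    dia = float(rng.uniform(35, 110))
    pp = float(rng.uniform(10, 90))
    return fuzzy.VitalSignSample(
        systolic_bp=dia + pp,
        diastolic_bp=dia,
        heart_rate=float(rng.uniform(35, 180)),
        spo2=float(rng.uniform(70, 100)),
    )
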