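"""Ordinal fall-risk level scales.

Two scales are used throughout the package:

* :class:`FiveLevelRisk` — the vital-sign (fuzzy) model's output,
  ``Normal < Low < Moderate < High < Emergency``.
* :class:`ThreeLevelRisk` — the ADL model's, the meta-model's, and the
  Morse Fall Scale's shared output, ``Low < Moderate < High``.

Levels are serialized as canonical capitalized strings (``"Normal"``,
``"Low"``, ...) in every file format; numeric codes are never written,
because several distinct weight maps assign numbers to the same level.
"""

from __future__ import annotations

from enum import IntEnum

from .errors import InvalidInputError


class FiveLevelRisk(IntEnum):
    """Five-level ordinal risk category emitted by the vital-sign model."""

    NORMAL = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3
    EMERGENCY = 4

    def __str__(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_name(cls, name: str) -> "FiveLevelRisk":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise InvalidInputError(
                f"unknown five-level risk category: {name!r}"
            ) from None


class ThreeLevelRisk(IntEnum):
    """Three-level ordinal risk category (ADL model, meta-model, MFS)."""

    LOW = 0
    MODERATE = 1
    HIGH = 2

    def __str__(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_name(cls, name: str) -> "ThreeLevelRisk":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise InvalidInputError(
                f"unknown three-level risk category: {name!r}"
            ) from None

    def to_five(self) -> FiveLevelRisk:
        """Embed into the five-level scale by shared category name."""
        return FiveLevelRisk[self.name]
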