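"""Blood-glucose classification and feedback-tier selection.

A reported value is classified by its measurement context.  Desired ranges
are 61–94 mg/dL fasting and 61–139 mg/dL one hour postprandial; values at
or below 60 mg/dL are critically low and values at or above 200 mg/dL are
critically high in either context.  The remaining values (95–199 fasting,
140–199 postprandial) are out of the desired range without being critical:
the reply still congratulates the participant for checking but asks her to
contact her care team, as do both critical tiers.

Values are integers (SMS replies); decimal inputs are rounded half-up
before classification.  The published boundaries leave exactly 60 mg/dL
unassigned (low is "<60" but desired ranges start at 61); it is treated as
critically low, the conservative choice for patient safety.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path

import yaml

from .catalog import MessageCategory

__all__ = [
    "Context",
    "Tier",
    "GlucoseThresholds",
    "GlucoseClassification",
    "ImplausibleValueError",
    "DEFAULT_THRESHOLDS",
    "classify",
    "tier_to_category",
    "load_thresholds",
]


class Context(str, enum.Enum):
    FASTING = "fasting"
    POSTPRANDIAL = "postprandial"


class Tier(str, enum.Enum):
    IN_RANGE = "in_range"
    OUT_OF_RANGE = "out_of_range"
    CRITICAL_LOW = "critical_low"
    CRITICAL_HIGH = "critical_high"


class ImplausibleValueError(ValueError):
    """Value outside the plausibility window; caller should ask again."""


@dataclasses.dataclass(frozen=True)
class GlucoseThresholds:
    """Classification boundaries in mg/dL, all bounds inclusive."""

    fasting_low: int = 61
    fasting_high: int = 94
    postprandial_low: int = 61
    postprandial_high: int = 139
    critical_low_max: int = 60
    critical_high_min: int = 200
    plausible_min: int = 20
    plausible_max: int = 600

    def __post_init__(self) -> None:
        if not (
            self.critical_low_max < self.fasting_low
            and self.critical_low_max < self.postprandial_low
        ):
            raise ValueError("critical_low_max must lie below the desired ranges")
        if not (
            self.critical_high_min > self.fasting_high
            and self.critical_high_min > self.postprandial_high
        ):
            raise ValueError("critical_high_min must lie above the desired ranges")
        if not (
            self.plausible_min
            <= self.critical_low_max
            < self.critical_high_min
            <= self.plausible_max
        ):
            raise ValueError("ranges must fall within the plausibility window")
        if self.fasting_low > self.fasting_high:
            raise ValueError("fasting range is empty")
        if self.postprandial_low > self.postprandial_high:
            raise ValueError("postprandial range is empty")

    def desired_range(self, context: Context) -> tuple[int, int]:
        if context is Context.FASTING:
            return self.fasting_low, self.fasting_high
        return self.postprandial_low, self.postprandial_high


DEFAULT_THRESHOLDS = GlucoseThresholds()


@dataclasses.dataclass(frozen=True)
class GlucoseClassification:
    context: Context
    value: int  # mg/dL, after rounding
    tier: Tier


def _round_half_up(value: float) -> int:
    return math.floor(value + 0.5)


def classify(
    value: float,
    context: Context,
    thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS,
) -> GlucoseClassification:
    """Assign exactly one feedback tier to a glucose value.

    Critical bounds apply in both contexts; the in-range band depends on
    whether the check was fasting or postprandial.  Raises
    :class:`ImplausibleValueError` outside the plausibility window, in
    which case the caller sends a clarification prompt instead of feedback.
    """
    context = Context(context)
    v = _round_half_up(float(value))
    if not thresholds.plausible_min <= v <= thresholds.plausible_max:
        raise ImplausibleValueError(
            f"{value} mg/dL is outside the plausible window "
            f"[{thresholds.plausible_min}, {thresholds.plausible_max}]"
        )
    if v <= thresholds.critical_low_max:
        tier = Tier.CRITICAL_LOW
    elif v >= thresholds.critical_high_min:
        tier = Tier.CRITICAL_HIGH
    else:
        lo, hi = thresholds.desired_range(context)
        tier = Tier.IN_RANGE if lo <= v <= hi else Tier.OUT_OF_RANGE
    return GlucoseClassification(context=context, value=v, tier=tier)


_TIER_CATEGORY: dict[Tier, MessageCategory] = {
    Tier.IN_RANGE: MessageCategory.FEEDBACK_IN_RANGE,
    Tier.OUT_OF_RANGE: MessageCategory.FEEDBACK_OUT_OF_RANGE,
    Tier.CRITICAL_LOW: MessageCategory.FEEDBACK_CRITICAL_LOW,
    Tier.CRITICAL_HIGH: MessageCategory.FEEDBACK_CRITICAL_HIGH,
}


def tier_to_category(tier: Tier) -> MessageCategory:
    """Map a classification tier to the message category that answers it."""
    return _TIER_CATEGORY[Tier(tier)]


def load_thresholds(path: str | Path) -> GlucoseThresholds:
    """Read threshold overrides from a YAML file; omitted keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(GlucoseThresholds)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return GlucoseThresholds(**{k: int(v) for k, v in raw.items()})
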