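"""Synthetic cohort generator.

Produces a roster, an inbound SMS stream, a glucometer device export and a
ground-truth record with controlled statistical structure, so the whole
engine and analytics stack can be exercised without any patient data.

Behavioral model, per participant and reminder slot:

* a glucose check occurs with probability ``check_prob`` (Bernoulli,
  independent across slots); the defaults emulate the pilot cohort — ten
  participants over fourteen program days with a seven-day pre-enrollment
  week, a 93% per-slot check rate and a 67.9% reply rate;
* each check writes a device record shortly after the reminder time (a
  truncated-normal delay: patients respond to the prompt, so readings
  follow it rather than scatter symmetrically around it);
* a performed check is texted back with conditional probability
  ``min(1, reply_prob / check_prob)``, making ``reply_prob`` the *marginal*
  probability that a reminder prompt receives a texted value while
  guaranteeing that every texted value corresponds to a real check;
* glucose values are drawn from context-dependent normals (fasting vs
  postprandial) with small critical-low/high tail mixtures, truncated to
  the plausible window and rounded to integers as an SMS reply would be.

Each participant gets an independent substream seeded by
``(seed, participant_index)``, so growing the cohort never reshuffles the
draws of existing participants.  Enrollment is at 05:00 local time, before
the earliest possible reminder slot, so the 24-hour quiet period ends
before the first slot of the next day and every participant accrues
exactly ``program_days`` complete 4-reminder days.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .engine import InboundMessage
from .glucose import Context
from .scheduler import (
    START_DELAY,
    Mealtimes,
    Participant,
    Slot,
    build_schedule,
)

__all__ = [
    "GlucoseModel",
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "recover_parameters",
]

_SLOT_CONTEXT = {
    Slot.FASTING: Context.FASTING,
    Slot.POST_BREAKFAST: Context.POSTPRANDIAL,
    Slot.POST_LUNCH: Context.POSTPRANDIAL,
    Slot.POST_DINNER: Context.POSTPRANDIAL,
}


class GlucoseModel(BaseModel):
    """Context-dependent value distributions (mg/dL)."""

    fasting_mean: float = 85.0
    fasting_sd: float = Field(8.0, gt=0)
    postprandial_mean: float = 115.0
    postprandial_sd: float = Field(18.0, gt=0)
    p_critical_low: float = Field(0.01, ge=0, le=1)
    p_critical_high: float = Field(0.02, ge=0, le=1)


class SimulationConfig(BaseModel):
    """All knobs of the generator; defaults are the emulated pilot cohort."""

    n_participants: int = Field(10, ge=1)
    program_days: int = Field(14, ge=1)
    pre_days: int = Field(7, ge=0)
    check_prob: float = Field(0.93, ge=0, le=1)
    pre_check_prob: float | None = Field(None, ge=0, le=1)
    reply_prob: float = Field(0.679, ge=0, le=1)
    glucose: GlucoseModel = GlucoseModel()
    check_delay_mean_min: float = 10.0
    check_delay_sd_min: float = Field(8.0, gt=0)
    start_date: date = date(2021, 6, 1)
    enrollment_time: time = time(5, 0)
    seed: int = 0

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be non-negative")
        return v


@dataclasses.dataclass
class SimulatedTruth:
    """Planted parameters and realized counts, for parameter-recovery tests."""

    config: SimulationConfig
    per_participant: dict[str, dict[str, int]]

    def totals(self) -> dict[str, int]:
        keys = ("slots", "checks", "replies", "pre_slots", "pre_checks")
        return {k: sum(d[k] for d in self.per_participant.values()) for k in keys}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": json.loads(self.config.model_dump_json()),
                    "per_participant": self.per_participant,
                    "totals": self.totals(),
                },
                indent=2,
            )
            + "\n"
        )


@dataclasses.dataclass
class SimulatedCohort:
    roster: list[Participant]
    inbound: list[InboundMessage]
    device: pd.DataFrame  # participant_id, datetime, glucose_mgdl
    truth: SimulatedTruth


def _mealtimes_for(index: int) -> Mealtimes:
    """Deterministic, varied mealtimes (stable under cohort-size changes)."""
    return Mealtimes(
        breakfast=_add_minutes(time(6, 45), (index * 17) % 120),
        lunch=_add_minutes(time(12, 0), (index * 13) % 90),
        dinner=_add_minutes(time(18, 0), (index * 11) % 90),
    )


def _add_minutes(t: time, minutes: int) -> time:
    dt = datetime.combine(date(2000, 1, 1), t) + timedelta(minutes=minutes)
    return dt.time()


def _draw_value(rng: np.random.Generator, context: Context, gm: GlucoseModel) -> int:
    u = rng.random()
    if u < gm.p_critical_low:
        return int(rng.integers(30, 60))
    if u < gm.p_critical_low + gm.p_critical_high:
        return int(rng.integers(200, 301))
    if context is Context.FASTING:
        v = rng.normal(gm.fasting_mean, gm.fasting_sd)
    else:
        v = rng.normal(gm.postprandial_mean, gm.postprandial_sd)
    return int(np.clip(round(v), 20, 600))


def _check_delay(rng: np.random.Generator, cfg: SimulationConfig) -> timedelta:
    minutes = rng.normal(cfg.check_delay_mean_min, cfg.check_delay_sd_min)
    return timedelta(minutes=float(max(1.0, minutes)))


_REPLY_STYLES = ("{v}", "{v} mg/dl", "My number is {v}")


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one synthetic cohort, fully reproducible from the seed."""
    reply_given_check = (
        min(1.0, config.reply_prob / config.check_prob)
        if config.check_prob > 0
        else 0.0
    )
    pre_p = (
        config.pre_check_prob
        if config.pre_check_prob is not None
        else config.check_prob
    )

    roster: list[Participant] = []
    inbound: list[InboundMessage] = []
    device_rows: list[tuple[str, datetime, int]] = []
    per_participant: dict[str, dict[str, int]] = {}

    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng([config.seed, i])
        mealtimes = _mealtimes_for(i)
        enrolled_at = datetime.combine(config.start_date, config.enrollment_time)
        participant = Participant(
            participant_id=pid,
            enrolled_at=enrolled_at,
            mealtimes=mealtimes,
            weekly_message_day=i % 7,
            program_days=config.program_days,
            recommended_checks_per_day=4,
        )
        roster.append(participant)

        # Onboarding answers: mealtimes texted back minutes after enrollment.
        for k, meal in enumerate(
            (mealtimes.breakfast, mealtimes.lunch, mealtimes.dinner)
        ):
            inbound.append(
                InboundMessage(
                    pid,
                    enrolled_at + timedelta(minutes=2 * (k + 1)),
                    meal.strftime("%H:%M"),
                )
            )

        stats = {"slots": 0, "checks": 0, "replies": 0, "pre_slots": 0, "pre_checks": 0}

        # Pre-enrollment week: checks at the would-be slot times, no texting
        # (the program is not yet active).
        for d in range(config.pre_days, 0, -1):
            day = enrolled_at.date() - timedelta(days=d)
            for slot in _SLOT_CONTEXT:
                stats["pre_slots"] += 1
                if rng.random() < pre_p:
                    stats["pre_checks"] += 1
                    when = mealtimes.slot_anchor(slot, day) + _check_delay(rng, config)
                    device_rows.append(
                        (pid, when, _draw_value(rng, _SLOT_CONTEXT[slot], config.glucose))
                    )

        # Program period: one Bernoulli check per scheduled reminder slot.
        events = build_schedule(
            participant, config.program_days, start=enrolled_at + START_DELAY
        )
        for event in events:
            if event.category != "reminder":
                continue
            stats["slots"] += 1
            if rng.random() >= config.check_prob:
                continue
            stats["checks"] += 1
            when = event.fire_at + _check_delay(rng, config)
            value = _draw_value(rng, _SLOT_CONTEXT[event.slot], config.glucose)
            device_rows.append((pid, when, value))
            if rng.random() < reply_given_check:
                stats["replies"] += 1
                style = _REPLY_STYLES[int(rng.choice(3, p=(0.8, 0.1, 0.1)))]
                inbound.append(
                    InboundMessage(
                        pid,
                        when + timedelta(minutes=float(rng.integers(1, 6))),
                        style.format(v=value),
                    )
                )
        per_participant[pid] = stats

    inbound.sort(key=lambda m: (m.received_at, m.participant_id))
    device = pd.DataFrame(
        device_rows, columns=["participant_id", "datetime", "glucose_mgdl"]
    ).sort_values(["participant_id", "datetime"], kind="stable").reset_index(drop=True)
    truth = SimulatedTruth(config=config, per_participant=per_participant)
    return SimulatedCohort(roster=roster, inbound=inbound, device=device, truth=truth)


def recover_parameters(truth: SimulatedTruth) -> dict[str, float]:
    """Empirical estimates of the planted rates.

    ``check_prob`` is checks over program-period slots; ``reply_prob`` is
    texted values over slots — the marginal per-prompt reply rate, matching
    how the engine's response rate is defined.
    """
    totals = truth.totals()
    slots = totals["slots"]
    return {
        "check_prob": totals["checks"] / slots if slots else 0.0,
        "reply_prob": totals["replies"] / slots if slots else 0.0,
    }
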