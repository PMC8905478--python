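"""Per-participant timetables of outbound messages.

Glucose reminders are anchored to the mealtimes a participant reports at
enrollment: a fasting prompt 30 minutes before breakfast, and postprandial
prompts one hour after breakfast, lunch and dinner — four prompts per day.
One educational and one motivational message go out each week at the
participant's chosen day and time.  No message is scheduled earlier than
24 hours after enrollment.

All times are naive local clock times at minute resolution: the program is
defined by clock-time rules ("30 minutes before breakfast"), so a single
local clock per participant is used and no time-zone arithmetic is done.
"""

from __future__ import annotations

import dataclasses
import enum
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Slot",
    "ParticipantStatus",
    "Mealtimes",
    "Participant",
    "ScheduledEvent",
    "ScheduleError",
    "build_schedule",
    "cancel_future",
    "read_roster",
    "write_roster",
]

#: Delay between enrollment and the first message a participant may receive.
START_DELAY = timedelta(hours=24)


class ScheduleError(ValueError):
    """Raised for invalid mealtimes or roster records."""


class Slot(str, enum.Enum):
    """Which of the four daily glucose checks a reminder refers to."""

    FASTING = "fasting"
    POST_BREAKFAST = "post_breakfast"
    POST_LUNCH = "post_lunch"
    POST_DINNER = "post_dinner"
    NONE = "none"


#: Reminder slots in within-day order (excludes NONE).
REMINDER_SLOTS: tuple[Slot, ...] = (
    Slot.FASTING,
    Slot.POST_BREAKFAST,
    Slot.POST_LUNCH,
    Slot.POST_DINNER,
)

#: Slot -> (anchor meal, offset). Fasting checks happen before the first
#: meal; postprandial checks one hour after each meal.
_SLOT_RULES: dict[Slot, tuple[str, timedelta]] = {
    Slot.FASTING: ("breakfast", timedelta(minutes=-30)),
    Slot.POST_BREAKFAST: ("breakfast", timedelta(minutes=60)),
    Slot.POST_LUNCH: ("lunch", timedelta(minutes=60)),
    Slot.POST_DINNER: ("dinner", timedelta(minutes=60)),
}


class ParticipantStatus(str, enum.Enum):
    ONBOARDING = "onboarding"
    ACTIVE = "active"
    UNSUBSCRIBED = "unsubscribed"
    COMPLETED = "completed"


# Opt-out is honored in any pre-terminal state, including onboarding.
_ALLOWED_TRANSITIONS = {
    (ParticipantStatus.ONBOARDING, ParticipantStatus.ACTIVE),
    (ParticipantStatus.ONBOARDING, ParticipantStatus.UNSUBSCRIBED),
    (ParticipantStatus.ACTIVE, ParticipantStatus.UNSUBSCRIBED),
    (ParticipantStatus.ACTIVE, ParticipantStatus.COMPLETED),
}


@dataclasses.dataclass(frozen=True)
class Mealtimes:
    """Reported clock times of the three daily meals (must be increasing)."""

    breakfast: time
    lunch: time
    dinner: time

    def __post_init__(self) -> None:
        if not (self.breakfast < self.lunch < self.dinner):
            raise ScheduleError(
                f"mealtimes must satisfy breakfast < lunch < dinner, got "
                f"{self.breakfast}, {self.lunch}, {self.dinner}"
            )

    def slot_anchor(self, slot: Slot, day: date) -> datetime:
        """Fire time of a reminder slot on the given calendar day."""
        meal, offset = _SLOT_RULES[slot]
        return datetime.combine(day, getattr(self, meal)) + offset


@dataclasses.dataclass
class Participant:
    """Enrollment state and messaging preferences for one woman.

    ``weekly_message_day`` uses Monday=0 .. Sunday=6.  ``mealtimes`` may be
    None while the participant is still answering onboarding questions.
    """

    participant_id: str
    enrolled_at: datetime
    mealtimes: Mealtimes | None = None
    language: str = "en"
    weekly_message_day: int = 0
    weekly_message_time: time = time(10, 0)
    program_days: int = 14
    status: ParticipantStatus = ParticipantStatus.ONBOARDING
    recommended_checks_per_day: int = 4

    def __post_init__(self) -> None:
        if self.program_days < 1:
            raise ScheduleError("program_days must be >= 1")
        if not 0 <= self.weekly_message_day <= 6:
            raise ScheduleError("weekly_message_day must be in 0..6 (Mon..Sun)")
        if self.recommended_checks_per_day < 1:
            raise ScheduleError("recommended_checks_per_day must be >= 1")

    def transition(self, new: ParticipantStatus) -> None:
        if (self.status, new) not in _ALLOWED_TRANSITIONS:
            raise ScheduleError(
                f"illegal status transition {self.status.value} -> {new.value}"
            )
        self.status = new


@dataclasses.dataclass(frozen=True, order=True)
class ScheduledEvent:
    """A planned outbound message: who, when, what kind, which slot."""

    fire_at: datetime
    participant_id: str
    category: str  # "reminder" | "educational" | "motivational"
    slot: Slot = Slot.NONE

    def __post_init__(self) -> None:
        if (self.category == "reminder") == (self.slot is Slot.NONE):
            raise ScheduleError("slot must be set iff category is reminder")


_CATEGORY_ORDER = {"reminder": 0, "educational": 1, "motivational": 2}


def build_schedule(
    participant: Participant,
    horizon_days: int,
    start: datetime | None = None,
) -> list[ScheduledEvent]:
    """Generate all outbound events for one participant.

    Events fall in the half-open window ``[start, start + horizon_days)``
    where ``start`` defaults to ``enrolled_at + 24 h`` and is never allowed
    to be earlier than that.  Because the window length is a whole number of
    days and every reminder slot recurs daily, each slot fires exactly
    ``horizon_days`` times regardless of how the window aligns with the
    clock; weekly messages fire ``horizon_days // 7`` times (for whole
    weeks).  Partial first calendar days are therefore allowed but the total
    count is exact.
    """
    if horizon_days < 1:
        raise ScheduleError("horizon_days must be >= 1")
    if participant.mealtimes is None:
        raise ScheduleError(
            f"participant {participant.participant_id} has no mealtimes"
        )
    earliest = participant.enrolled_at + START_DELAY
    start = earliest if start is None else max(start, earliest)
    end = start + timedelta(days=horizon_days)

    events: list[ScheduledEvent] = []
    day = start.date() - timedelta(days=1)
    last = end.date() + timedelta(days=1)
    while day <= last:
        for slot in REMINDER_SLOTS:
            fire = participant.mealtimes.slot_anchor(slot, day)
            if start <= fire < end:
                events.append(
                    ScheduledEvent(fire, participant.participant_id, "reminder", slot)
                )
        if day.weekday() == participant.weekly_message_day:
            fire = datetime.combine(day, participant.weekly_message_time)
            if start <= fire < end:
                for cat in ("educational", "motivational"):
                    events.append(
                        ScheduledEvent(fire, participant.participant_id, cat)
                    )
        day += timedelta(days=1)

    events.sort(key=lambda e: (e.fire_at, _CATEGORY_ORDER[e.category]))
    return events


def cancel_future(
    schedule: Iterable[ScheduledEvent], participant_id: str, as_of: datetime
) -> list[ScheduledEvent]:
    """Drop every event for ``participant_id`` strictly after ``as_of``.

    Idempotent; events for other participants and past events are untouched.
    """
    return [
        e
        for e in schedule
        if e.participant_id != participant_id or e.fire_at <= as_of
    ]


# ---------------------------------------------------------------------------
# Roster file I/O (YAML, one record per participant)

def _parse_hhmm(value: str) -> time:
    try:
        hh, mm = str(value).split(":")
        return time(int(hh), int(mm))
    except Exception as exc:  # noqa: BLE001 - normalize to domain error
        raise ScheduleError(f"invalid HH:MM time: {value!r}") from exc


def read_roster(path: str | Path) -> list[Participant]:
    """Read a participant roster from a YAML file.

    Each record requires participant_id, enrolled_at (ISO-8601), mealtimes
    (HH:MM strings) and recommended_checks_per_day; an absent
    recommended-checks field is an error naming the participant, because
    adherence is undefined without it.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ScheduleError("roster file must contain a list of records")
    roster = []
    for rec in raw:
        pid = rec.get("participant_id")
        if not pid:
            raise ScheduleError("roster record missing participant_id")
        if "recommended_checks_per_day" not in rec:
            raise ScheduleError(
                f"participant {pid}: missing recommended_checks_per_day"
            )
        meals = rec.get("mealtimes") or {}
        mealtimes = (
            Mealtimes(
                _parse_hhmm(meals["breakfast"]),
                _parse_hhmm(meals["lunch"]),
                _parse_hhmm(meals["dinner"]),
            )
            if meals
            else None
        )
        roster.append(
            Participant(
                participant_id=str(pid),
                enrolled_at=datetime.fromisoformat(rec["enrolled_at"]),
                mealtimes=mealtimes,
                language=rec.get("language", "en"),
                weekly_message_day=int(rec.get("weekly_message_day", 0)),
                weekly_message_time=_parse_hhmm(
                    rec.get("weekly_message_time", "10:00")
                ),
                program_days=int(rec.get("program_days", 14)),
                recommended_checks_per_day=int(rec["recommended_checks_per_day"]),
            )
        )
    return roster


def write_roster(roster: Sequence[Participant], path: str | Path) -> None:
    records = []
    for p in roster:
        rec: dict = {
            "participant_id": p.participant_id,
            "language": p.language,
            "enrolled_at": p.enrolled_at.isoformat(),
            "weekly_message_day": p.weekly_message_day,
            "weekly_message_time": p.weekly_message_time.strftime("%H:%M"),
            "program_days": p.program_days,
            "recommended_checks_per_day": p.recommended_checks_per_day,
        }
        if p.mealtimes is not None:
            rec["mealtimes"] = {
                "breakfast": p.mealtimes.breakfast.strftime("%H:%M"),
                "lunch": p.mealtimes.lunch.strftime("%H:%M"),
                "dinner": p.mealtimes.dinner.strftime("%H:%M"),
            }
        records.append(rec)
    Path(path).write_text(yaml.safe_dump(records, sort_keys=False))
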