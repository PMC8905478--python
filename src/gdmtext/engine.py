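"""Two-way conversation state machine.

The engine is deliberately a *pure* state machine: time advances only when
the caller invokes :meth:`Engine.tick`, so replaying the same roster and
inbound stream always produces a byte-identical message log.  There is no
wall-clock dependency and no transport — outbound messages are appended to
an ordered JSON-lines log; a real SMS gateway would sit behind a sink that
consumes that log.

Lifecycle of one participant:

1. ``enroll`` — welcome text (with STOP opt-out info), a disclaimer that
   the account is not monitored by a clinician in real time, then the first
   onboarding question (breakfast time).
2. Onboarding answers (HH:MM texts) record breakfast, lunch and dinner;
   after the third answer the participant becomes active and her reminder
   and weekly-message schedule is built, starting no earlier than 24 hours
   after enrollment.
3. ``tick`` dispatches due scheduled events; each reminder registers as the
   pending prompt for its slot.
4. Glucose replies are linked to the most recent unanswered reminder within
   a configurable window (default 3 h) to resolve fasting vs postprandial
   context, classified, and answered with tiered feedback.
5. "STOP" (any case) cancels all future messages after a single
   acknowledgment.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import json
import logging
import re
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import Catalog, MessageCategory, load_catalog
from .glucose import (
    DEFAULT_THRESHOLDS,
    Context,
    GlucoseThresholds,
    classify,
    tier_to_category,
)
from .scheduler import (
    START_DELAY,
    Mealtimes,
    Participant,
    ParticipantStatus,
    ScheduledEvent,
    Slot,
    build_schedule,
    cancel_future,
)

__all__ = [
    "Engine",
    "EngineError",
    "UndefinedRateError",
    "InboundMessage",
    "ParsedReply",
    "ParsedKind",
    "LogEntry",
    "parse_inbound",
    "response_rate",
    "replay",
    "write_log",
    "read_log",
]

logger = logging.getLogger(__name__)

# Bodies the engine owns rather than the catalog: operational plumbing the
# deployed program needed but whose wording is not part of the catalog's
# clinical content.
CLARIFICATION_BODY = (
    "Sorry, we did not understand your message. "
    "Please reply with your number only."
)
STOP_ACK_BODY = (
    "You have been unsubscribed and will not receive any more messages. "
    "Please contact your care team with any questions."
)

_SLOT_CONTEXT = {
    Slot.FASTING: Context.FASTING,
    Slot.POST_BREAKFAST: Context.POSTPRANDIAL,
    Slot.POST_LUNCH: Context.POSTPRANDIAL,
    Slot.POST_DINNER: Context.POSTPRANDIAL,
}
_SLOT_REMINDER_RANK = {
    Slot.FASTING: 0,
    Slot.POST_BREAKFAST: 1,
    Slot.POST_LUNCH: 2,
    Slot.POST_DINNER: 3,
}
_ONBOARDING_MEALS = ("breakfast", "lunch", "dinner")


class EngineError(ValueError):
    pass


class UndefinedRateError(ZeroDivisionError):
    """Response rate requested over a log with no qualifying prompts."""


# ---------------------------------------------------------------------------
# Inbound parsing

class ParsedKind(str, enum.Enum):
    GLUCOSE_VALUE = "glucose_value"
    STOP = "stop"
    ONBOARDING_ANSWER = "onboarding_answer"
    UNRECOGNIZED = "unrecognized"


@dataclasses.dataclass(frozen=True)
class ParsedReply:
    kind: ParsedKind
    value: int | None = None  # mg/dL, glucose_value only
    answer_time: time | None = None  # onboarding_answer only


@dataclasses.dataclass(frozen=True)
class InboundMessage:
    participant_id: str
    received_at: datetime
    text: str


_TIME_RE = re.compile(r"\b(\d{1,2}):(\d{2})\b")
# One whitespace-delimited word: optional leading punctuation, a number,
# an optional glued unit, trailing punctuation.  "142", "142mg/dl", "95."
_NUMBER_WORD_RE = re.compile(
    r"^[\(\[]*(\d+(?:\.\d+)?)(?:\s*mg/?dl)?[\)\]\.,!?;:]*$", re.IGNORECASE
)


def parse_inbound(text: str, onboarding: bool = False) -> ParsedReply:
    """Interpret a raw SMS reply.

    "STOP" (trimmed, any case) always wins.  During onboarding an HH:MM
    token is a mealtime answer.  Otherwise the first whitespace-delimited
    numeric token in the plausible glucose window 20–600 mg/dL (units such
    as "mg/dl" are ignored, decimals rounded half-up) is a glucose value.
    Anything else is unrecognized — a value, not an error.
    """
    stripped = text.strip()
    if stripped.casefold().rstrip(".!") == "stop":
        return ParsedReply(ParsedKind.STOP)
    if onboarding:
        m = _TIME_RE.search(stripped)
        if m:
            hh, mm = int(m.group(1)), int(m.group(2))
            if hh < 24 and mm < 60:
                return ParsedReply(
                    ParsedKind.ONBOARDING_ANSWER, answer_time=time(hh, mm)
                )
    for word in stripped.split():
        m = _NUMBER_WORD_RE.match(word)
        if m:
            value = int(float(m.group(1)) + 0.5)
            if (
                DEFAULT_THRESHOLDS.plausible_min
                <= value
                <= DEFAULT_THRESHOLDS.plausible_max
            ):
                return ParsedReply(ParsedKind.GLUCOSE_VALUE, value=value)
    return ParsedReply(ParsedKind.UNRECOGNIZED)


# ---------------------------------------------------------------------------
# Message log

@dataclasses.dataclass(frozen=True)
class LogEntry:
    """One message in the append-only log, inbound or outbound.

    For an outbound reminder, ``slot`` names the glucose check it prompts.
    For an inbound glucose reply, ``in_reply_to`` is the seq of the reminder
    it answers (if linked); for outbound feedback it is the seq of the
    inbound message being answered.
    """

    seq: int
    timestamp: datetime
    direction: str  # "in" | "out"
    participant_id: str
    category: str
    slot: str | None
    body: str
    in_reply_to: int | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "seq": self.seq,
                "timestamp": self.timestamp.isoformat(),
                "direction": self.direction,
                "participant_id": self.participant_id,
                "category": self.category,
                "slot": self.slot,
                "body": self.body,
                "in_reply_to": self.in_reply_to,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "LogEntry":
        d = json.loads(line)
        return cls(
            seq=d["seq"],
            timestamp=datetime.fromisoformat(d["timestamp"]),
            direction=d["direction"],
            participant_id=d["participant_id"],
            category=d["category"],
            slot=d.get("slot"),
            body=d.get("body", ""),
            in_reply_to=d.get("in_reply_to"),
        )


def write_log(log: Sequence[LogEntry], path: str | Path) -> None:
    Path(path).write_text("".join(e.to_json() + "\n" for e in log))


def read_log(path: str | Path) -> list[LogEntry]:
    return [
        LogEntry.from_json(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


@dataclasses.dataclass
class _PendingReminder:
    seq: int
    fire_at: datetime
    slot: Slot
    answered: bool = False
    clarified: bool = False


# ---------------------------------------------------------------------------
# Engine

class Engine:
    """Event-driven dispatcher and reply handler for a participant cohort."""

    def __init__(
        self,
        catalog: Catalog | None = None,
        thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS,
        linkage_window: timedelta = timedelta(hours=3),
    ):
        self.catalog = catalog if catalog is not None else load_catalog()
        self.thresholds = thresholds
        self.linkage_window = linkage_window
        self.participants: dict[str, Participant] = {}
        self.schedule: list[ScheduledEvent] = []
        self.log: list[LogEntry] = []
        self._pending: dict[str, dict[Slot, _PendingReminder]] = {}
        self._onboarding: dict[str, dict[str, time]] = {}
        self._last_tick: datetime | None = None
        self._seq = 0

    # -- low-level ----------------------------------------------------------

    def _append(
        self,
        direction: str,
        at: datetime,
        participant_id: str,
        category: str,
        body: str,
        slot: Slot | None = None,
        in_reply_to: int | None = None,
    ) -> LogEntry:
        self._seq += 1
        entry = LogEntry(
            seq=self._seq,
            timestamp=at,
            direction=direction,
            participant_id=participant_id,
            category=category,
            slot=None if slot in (None, Slot.NONE) else slot.value,
            body=body,
            in_reply_to=in_reply_to,
        )
        self.log.append(entry)
        return entry

    def _send(
        self,
        participant: Participant,
        category: str,
        body: str,
        at: datetime,
        slot: Slot | None = None,
        in_reply_to: int | None = None,
    ) -> LogEntry | None:
        # Unsubscribed participants receive nothing (the STOP ack is sent
        # before the status flips).
        if participant.status is ParticipantStatus.UNSUBSCRIBED:
            return None
        return self._append(
            "out", at, participant.participant_id, category, body, slot, in_reply_to
        )

    def _template_body(self, participant: Participant, category: MessageCategory,
                       rank: int | None = None) -> str:
        group = self.catalog.group(category, participant.language)
        if not group:
            group = self.catalog.group(category, "en")  # language fallback
        if rank is not None and rank < len(group):
            return group[rank].body
        return group[0].body

    # -- enrollment ----------------------------------------------------------

    def enroll(self, participant: Participant, skip_onboarding: bool = False) -> None:
        """Register a participant and send the welcome sequence.

        With ``skip_onboarding`` (mealtimes already known, e.g. collected on
        paper), the participant is activated immediately and no mealtime
        questions are texted; reminders still start 24 h after enrollment.
        """
        pid = participant.participant_id
        if pid in self.participants:
            raise EngineError(f"participant {pid} already enrolled")
        if skip_onboarding and participant.mealtimes is None:
            raise EngineError("skip_onboarding requires mealtimes")
        self.participants[pid] = participant
        at = participant.enrolled_at
        self._send(
            participant, MessageCategory.WELCOME.value,
            self._template_body(participant, MessageCategory.WELCOME), at,
        )
        self._send(
            participant, MessageCategory.DISCLAIMER.value,
            self._template_body(participant, MessageCategory.DISCLAIMER), at,
        )
        if skip_onboarding:
            self._activate(participant, at)
        else:
            self._onboarding[pid] = {}
            self._send(
                participant, MessageCategory.ONBOARDING_QUESTION.value,
                self._template_body(participant, MessageCategory.ONBOARDING_QUESTION, 0),
                at,
            )

    def _activate(self, participant: Participant, at: datetime) -> None:
        participant.transition(ParticipantStatus.ACTIVE)
        start = max(participant.enrolled_at + START_DELAY, at)
        self.schedule.extend(
            build_schedule(participant, participant.program_days, start=start)
        )
        self.schedule.sort(key=lambda e: (e.fire_at, e.participant_id))

    # -- time ----------------------------------------------------------------

    def tick(self, now: datetime) -> None:
        """Dispatch every scheduled event due at or before ``now``.

        Monotone in time; ticking twice at the same instant is a no-op
        because dispatched events leave the pending schedule.
        """
        if self._last_tick is not None and now < self._last_tick:
            raise EngineError("tick must not move backwards in time")
        self._last_tick = now
        due = [e for e in self.schedule if e.fire_at <= now]
        if not due:
            return
        self.schedule = [e for e in self.schedule if e.fire_at > now]
        for event in due:
            participant = self.participants[event.participant_id]
            if participant.status is not ParticipantStatus.ACTIVE:
                continue
            if event.category == "reminder":
                body = self._template_body(
                    participant, MessageCategory.REMINDER,
                    _SLOT_REMINDER_RANK[event.slot],
                )
                entry = self._send(
                    participant, "reminder", body, event.fire_at, slot=event.slot
                )
                if entry is not None:
                    self._pending.setdefault(event.participant_id, {})[event.slot] = (
                        _PendingReminder(entry.seq, event.fire_at, event.slot)
                    )
            else:
                template = self.catalog.next_message(
                    event.participant_id,
                    MessageCategory(event.category),
                    participant.language,
                )
                self._send(participant, event.category, template.body, event.fire_at)

    # -- inbound --------------------------------------------------------------

    def _find_pending(self, pid: str, received_at: datetime) -> _PendingReminder | None:
        """Most recent unanswered reminder within the linkage window."""
        candidates = [
            p
            for p in self._pending.get(pid, {}).values()
            if not p.answered
            and timedelta(0) <= received_at - p.fire_at <= self.linkage_window
        ]
        return max(candidates, key=lambda p: p.fire_at) if candidates else None

    def link_context(self, participant_id: str, received_at: datetime) -> Context:
        """Resolve the measurement context of a reported value.

        A pending reminder within the linkage window decides (fasting slot
        -> fasting, others -> postprandial); an orphan value falls back to
        time of day relative to the reported breakfast time.
        """
        pending = self._find_pending(participant_id, received_at)
        if pending is not None:
            return _SLOT_CONTEXT[pending.slot]
        participant = self.participants[participant_id]
        breakfast = (
            participant.mealtimes.breakfast
            if participant.mealtimes is not None
            else time(8, 0)
        )
        return (
            Context.FASTING
            if received_at.time() < breakfast
            else Context.POSTPRANDIAL
        )

    def handle_inbound(self, msg: InboundMessage) -> None:
        """Process one inbound text and append any automatic response."""
        participant = self.participants.get(msg.participant_id)
        if participant is None:
            logger.warning(
                "dropping message from unknown participant %r", msg.participant_id
            )
            return
        parsed = parse_inbound(
            msg.text, onboarding=participant.status is ParticipantStatus.ONBOARDING
        )

        if parsed.kind is ParsedKind.GLUCOSE_VALUE:
            pending = self._find_pending(msg.participant_id, msg.received_at)
            inbound = self._append(
                "in", msg.received_at, msg.participant_id, "glucose_value",
                msg.text, in_reply_to=pending.seq if pending else None,
            )
            if participant.status is ParticipantStatus.UNSUBSCRIBED:
                return
            context = (
                _SLOT_CONTEXT[pending.slot]
                if pending is not None
                else self.link_context(msg.participant_id, msg.received_at)
            )
            classification = classify(parsed.value, context, self.thresholds)
            template = self.catalog.next_feedback(
                msg.participant_id, classification.tier, participant.language
            )
            sent = self._send(
                participant,
                tier_to_category(classification.tier).value,
                template.body,
                msg.received_at,
                in_reply_to=inbound.seq,
            )
            if sent is not None and pending is not None:
                pending.answered = True
            return

        self._append(
            "in", msg.received_at, msg.participant_id, parsed.kind.value, msg.text
        )
        if participant.status is ParticipantStatus.UNSUBSCRIBED:
            return

        if parsed.kind is ParsedKind.STOP:
            self._send(participant, "stop_ack", STOP_ACK_BODY, msg.received_at)
            self.schedule = cancel_future(
                self.schedule, msg.participant_id, msg.received_at
            )
            self._pending.pop(msg.participant_id, None)
            participant.transition(ParticipantStatus.UNSUBSCRIBED)
            return

        if parsed.kind is ParsedKind.ONBOARDING_ANSWER and (
            participant.status is ParticipantStatus.ONBOARDING
        ):
            answers = self._onboarding.setdefault(msg.participant_id, {})
            answers[_ONBOARDING_MEALS[len(answers)]] = parsed.answer_time
            if len(answers) < len(_ONBOARDING_MEALS):
                self._send(
                    participant, MessageCategory.ONBOARDING_QUESTION.value,
                    self._template_body(
                        participant, MessageCategory.ONBOARDING_QUESTION, len(answers)
                    ),
                    msg.received_at,
                )
                return
            try:
                participant.mealtimes = Mealtimes(**answers)
            except Exception:
                # Out-of-order answers: start the questions over.
                self._onboarding[msg.participant_id] = {}
                self._send(
                    participant, MessageCategory.ONBOARDING_QUESTION.value,
                    self._template_body(
                        participant, MessageCategory.ONBOARDING_QUESTION, 0
                    ),
                    msg.received_at,
                )
                return
            del self._onboarding[msg.participant_id]
            self._activate(participant, msg.received_at)
            return

        # Unrecognized: at most one clarification prompt per pending reminder.
        pending = self._find_pending(msg.participant_id, msg.received_at)
        if pending is not None and not pending.clarified:
            self._send(
                participant, "clarification", CLARIFICATION_BODY, msg.received_at
            )
            pending.clarified = True

    # -- maintenance -----------------------------------------------------------

    def finalize(self, now: datetime) -> None:
        """Mark active participants whose program window has ended complete."""
        for p in self.participants.values():
            if p.status is ParticipantStatus.ACTIVE and not any(
                e.participant_id == p.participant_id for e in self.schedule
            ):
                end = p.enrolled_at + START_DELAY + timedelta(days=p.program_days)
                if now >= end:
                    p.transition(ParticipantStatus.COMPLETED)


# ---------------------------------------------------------------------------
# Log analytics

def response_rate(
    log: Iterable[LogEntry], categories: frozenset[str] | set[str] = frozenset({"reminder"})
) -> float:
    """Percent of reply-requesting outbound messages that got a linked reply.

    By default only glucose reminders count in the denominator — they are
    the messages that explicitly ask for a texted number.  Returned as a
    percent rounded to one decimal.
    """
    log = list(log)
    prompts = {e.seq for e in log if e.direction == "out" and e.category in categories}
    if not prompts:
        raise UndefinedRateError("no reply-requesting messages in these categories")
    answered = {
        e.in_reply_to
        for e in log
        if e.direction == "in" and e.in_reply_to in prompts
    }
    return round(100.0 * len(answered) / len(prompts), 1)


# ---------------------------------------------------------------------------
# Replay

def replay(
    roster: Sequence[Participant],
    inbound: Sequence[InboundMessage],
    catalog: Catalog | None = None,
    thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS,
) -> Engine:
    """Run a full cohort through the engine from enrollments to completion.

    Enrollments and inbound messages are interleaved in timestamp order
    (ties: enrollment first, then stream order); the clock then advances
    past every remaining scheduled event.  Deterministic for fixed inputs.
    """
    eng = Engine(catalog=catalog, thresholds=thresholds)
    # Participants are copied so replaying never mutates the caller's roster
    # (status transitions and onboarding answers stay inside the engine).
    events: list[tuple[datetime, int, int, object]] = [
        (p.enrolled_at, 0, i, copy.deepcopy(p)) for i, p in enumerate(roster)
    ] + [(m.received_at, 1, i, m) for i, m in enumerate(inbound)]
    events.sort(key=lambda t: t[:3])
    for when, kind, _, payload in events:
        eng.tick(when)
        if kind == 0:
            eng.enroll(payload)  # type: ignore[arg-type]
        else:
            eng.handle_inbound(payload)  # type: ignore[arg-type]
    if roster:
        end = max(
            p.enrolled_at + START_DELAY + timedelta(days=p.program_days + 1)
            for p in roster
        )
        eng.tick(end)
        eng.finalize(end)
    return eng
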