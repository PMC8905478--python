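"""Conversation state machine: onboarding, linkage, STOP, replay, rates."""

from __future__ import annotations

from datetime import datetime, time, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gdmtext import (
    Engine,
    EngineError,
    InboundMessage,
    ParsedKind,
    ParticipantStatus,
    parse_inbound,
    read_log,
    replay,
    response_rate,
    write_log,
)
from gdmtext.engine import UndefinedRateError
from gdmtext.simulate import SimulationConfig, simulate_cohort

from conftest import make_participant, make_prompt_log


# ---------------------------------------------------------------------------
# parse_inbound: a hand-labelled corpus of reply strings

CORPUS = [
    ("stop", ParsedKind.STOP, None),
    ("STOP ", ParsedKind.STOP, None),
    ("  Stop.", ParsedKind.STOP, None),
    ("stop!", ParsedKind.STOP, None),
    ("please stop", ParsedKind.UNRECOGNIZED, None),  # STOP must stand alone
    ("95", ParsedKind.GLUCOSE_VALUE, 95),
    (" 142 ", ParsedKind.GLUCOSE_VALUE, 142),
    ("my number is 142 mg/dl", ParsedKind.GLUCOSE_VALUE, 142),
    ("142mg/dl", ParsedKind.GLUCOSE_VALUE, 142),
    ("142 MG/DL", ParsedKind.GLUCOSE_VALUE, 142),
    ("it was 88.", ParsedKind.GLUCOSE_VALUE, 88),
    ("88!", ParsedKind.GLUCOSE_VALUE, 88),
    ("(95)", ParsedKind.GLUCOSE_VALUE, 95),
    ("95.5", ParsedKind.GLUCOSE_VALUE, 96),  # decimals round half-up
    ("120.4", ParsedKind.GLUCOSE_VALUE, 120),
    ("glucose 101 after lunch", ParsedKind.GLUCOSE_VALUE, 101),
    ("around 200 i think", ParsedKind.GLUCOSE_VALUE, 200),
    ("600", ParsedKind.GLUCOSE_VALUE, 600),
    ("20", ParsedKind.GLUCOSE_VALUE, 20),
    ("hello??", ParsedKind.UNRECOGNIZED, None),
    ("", ParsedKind.UNRECOGNIZED, None),
    ("9", ParsedKind.UNRECOGNIZED, None),  # below plausibility
    ("19", ParsedKind.UNRECOGNIZED, None),
    ("601", ParsedKind.UNRECOGNIZED, None),  # above plausibility
    ("1000", ParsedKind.UNRECOGNIZED, None),
    ("ate at 8:00", ParsedKind.UNRECOGNIZED, None),  # time, not glucose
    ("thanks", ParsedKind.UNRECOGNIZED, None),
    ("no reading today", ParsedKind.UNRECOGNIZED, None),
    ("7 then 95", ParsedKind.GLUCOSE_VALUE, 95),  # first plausible token
    ("95 then 110", ParsedKind.GLUCOSE_VALUE, 95),
]


@pytest.mark.parametrize(("text", "kind", "value"), CORPUS)
def test_parse_inbound_corpus(text, kind, value):
    parsed = parse_inbound(text)
    assert parsed.kind is kind
    assert parsed.value == value


@pytest.mark.parametrize(
    ("text", "expected"),
    [("8:00", time(8, 0)), ("I eat at 12:30 usually", time(12, 30)),
     ("19:05", time(19, 5))],
)
def test_parse_onboarding_times(text, expected):
    parsed = parse_inbound(text, onboarding=True)
    assert parsed.kind is ParsedKind.ONBOARDING_ANSWER
    assert parsed.answer_time == expected


def test_onboarding_flag_does_not_eat_plain_numbers():
    parsed = parse_inbound("95", onboarding=True)
    assert parsed.kind is ParsedKind.GLUCOSE_VALUE


@given(st.sampled_from(["stop", "Stop", "STOP", "sToP"]),
       st.sampled_from(["", " ", "  "]))
def test_stop_any_case_any_padding(word, pad):
    assert parse_inbound(pad + word + pad).kind is ParsedKind.STOP


# ---------------------------------------------------------------------------
# Enrollment and onboarding

def onboard(engine: Engine, pid: str, at: datetime) -> None:
    for minutes, answer in ((2, "8:00"), (4, "12:30"), (6, "19:00")):
        engine.handle_inbound(
            InboundMessage(pid, at + timedelta(minutes=minutes), answer)
        )


def test_enroll_sends_welcome_then_disclaimer_then_question():
    engine = Engine()
    p = make_participant("P01")
    p.mealtimes = None
    engine.enroll(p)
    categories = [e.category for e in engine.log if e.direction == "out"]
    assert categories[:2] == ["welcome", "disclaimer"]
    assert categories[2] == "onboarding_question"
    assert "STOP" in engine.log[0].body  # opt-out info in the welcome
    assert "not monitored by a clinician" in engine.log[1].body


def test_onboarding_records_mealtimes_and_activates():
    engine = Engine()
    p = make_participant("P01")
    p.mealtimes = None
    engine.enroll(p)
    onboard(engine, "P01", p.enrolled_at)
    assert p.status is ParticipantStatus.ACTIVE
    assert p.mealtimes.breakfast == time(8, 0)
    assert p.mealtimes.dinner == time(19, 0)
    # reminders scheduled only from 24 h after enrollment
    assert min(e.fire_at for e in engine.schedule) >= p.enrolled_at + timedelta(hours=24)
    assert sum(e.category == "reminder" for e in engine.schedule) == 56


def test_duplicate_enrollment_rejected_state_unchanged():
    engine = Engine()
    engine.enroll(make_participant("P01"), skip_onboarding=True)
    log_before = list(engine.log)
    with pytest.raises(EngineError, match="already enrolled"):
        engine.enroll(make_participant("P01"), skip_onboarding=True)
    assert engine.log == log_before


# ---------------------------------------------------------------------------
# Dispatch, linkage and feedback

def active_engine() -> tuple[Engine, datetime]:
    engine = Engine()
    p = make_participant("P01")
    engine.enroll(p, skip_onboarding=True)
    first_fasting = datetime(2021, 6, 2, 7, 30)
    engine.tick(first_fasting)
    return engine, first_fasting


def test_tick_dispatches_due_reminder_once():
    engine, at = active_engine()
    reminders = [e for e in engine.log if e.category == "reminder"]
    assert len(reminders) == 1
    assert reminders[0].slot == "fasting"
    assert reminders[0].timestamp == at
    engine.tick(at)  # same instant again: no duplicates
    assert sum(e.category == "reminder" for e in engine.log) == 1


def test_in_range_reply_gets_rotating_feedback_linked_both_ways():
    engine, at = active_engine()
    engine.handle_inbound(InboundMessage("P01", at + timedelta(minutes=40), "85"))
    inbound = next(e for e in engine.log if e.direction == "in")
    feedback = next(e for e in engine.log if e.category == "feedback_in_range")
    reminder = next(e for e in engine.log if e.category == "reminder")
    assert inbound.in_reply_to == reminder.seq
    assert feedback.in_reply_to == inbound.seq
    assert inbound.body == "85"  # raw text preserved verbatim


def test_critical_high_reply_after_lunch_prompt():
    engine, _ = active_engine()
    lunch_prompt = datetime(2021, 6, 2, 13, 30)
    engine.tick(lunch_prompt)
    engine.handle_inbound(
        InboundMessage("P01", lunch_prompt + timedelta(minutes=30), "210")
    )
    feedback = [e for e in engine.log if e.category.startswith("feedback")]
    assert [e.category for e in feedback] == ["feedback_critical_high"]
    assert "care team" in feedback[0].body


def test_orphan_value_context_falls_back_to_time_of_day():
    engine, at = active_engine()
    # answer the fasting prompt so nothing is pending
    engine.handle_inbound(InboundMessage("P01", at + timedelta(minutes=10), "85"))
    assert engine.link_context("P01", datetime(2021, 6, 2, 6, 10)).value == "fasting"
    assert engine.link_context("P01", datetime(2021, 6, 2, 15, 0)).value == "postprandial"


def test_reminder_older_than_window_is_not_linked():
    engine, at = active_engine()
    engine.handle_inbound(InboundMessage("P01", at + timedelta(hours=4), "130"))
    inbound = next(e for e in engine.log if e.direction == "in")
    assert inbound.in_reply_to is None  # 3-hour linkage window elapsed
    # fallback at 11:30 is postprandial, so 130 is in range
    assert any(e.category == "feedback_in_range" for e in engine.log)


def test_unrecognized_gets_one_clarification_per_pending_reminder():
    engine, at = active_engine()
    for minutes in (5, 10, 15):
        engine.handle_inbound(
            InboundMessage("P01", at + timedelta(minutes=minutes), "hello??")
        )
    clarifications = [e for e in engine.log if e.category == "clarification"]
    assert len(clarifications) == 1
    assert "number only" in clarifications[0].body


def test_unknown_sender_logged_and_dropped():
    engine, at = active_engine()
    n = len(engine.log)
    engine.handle_inbound(InboundMessage("GHOST", at, "95"))
    assert len(engine.log) == n


def test_stop_cancels_everything_and_silences_forever():
    engine, at = active_engine()
    engine.handle_inbound(InboundMessage("P01", at + timedelta(minutes=5), "STOP"))
    stop_seq = [e for e in engine.log if e.category == "stop_ack"]
    assert len(stop_seq) == 1
    engine.tick(at + timedelta(days=20))
    engine.handle_inbound(InboundMessage("P01", at + timedelta(days=20), "95"))
    after_ack = [
        e for e in engine.log
        if e.direction == "out" and e.seq > stop_seq[0].seq
    ]
    assert after_ack == []
    assert engine.participants["P01"].status is ParticipantStatus.UNSUBSCRIBED


@given(texts=st.lists(
    st.sampled_from(["95", "hello??", "210", "STOP", "50", "8:00"]),
    min_size=1, max_size=12,
))
def test_post_stop_silence_for_any_event_sequence(texts):
    """No outbound message besides the acknowledgment ever follows a STOP."""
    engine, at = active_engine()
    when = at
    for text in texts + ["STOP"]:
        when += timedelta(minutes=3)
        engine.handle_inbound(InboundMessage("P01", when, text))
    engine.tick(when + timedelta(days=30))
    ack_seq = next(e.seq for e in engine.log if e.category == "stop_ack")
    assert not any(
        e.direction == "out" and e.seq > ack_seq for e in engine.log
    )


def test_glucose_conservation_every_value_gets_exactly_one_feedback():
    """Each inbound glucose text produces exactly one feedback message and
    every feedback message references exactly one inbound text."""
    cohort = simulate_cohort(SimulationConfig(n_participants=4, program_days=5, seed=5))
    state = replay(cohort.roster, cohort.inbound)
    glucose_in = [e for e in state.log if e.direction == "in" and e.category == "glucose_value"]
    feedback = [e for e in state.log if e.category.startswith("feedback")]
    assert len(feedback) == len(glucose_in)
    assert sorted(e.in_reply_to for e in feedback) == sorted(e.seq for e in glucose_in)


def test_replay_is_deterministic_byte_for_byte(tmp_path):
    cohort = simulate_cohort(SimulationConfig(n_participants=3, program_days=4, seed=9))
    a = replay(cohort.roster, cohort.inbound)
    b = replay(cohort.roster, cohort.inbound)
    pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    write_log(a.log, pa)
    write_log(b.log, pb)
    assert pa.read_bytes() == pb.read_bytes()
    assert read_log(pa) == a.log  # log round-trips through JSON-lines


# ---------------------------------------------------------------------------
# Response rate

def test_response_rate_reproduces_cohort_arithmetic():
    log = make_prompt_log(560, 380)
    assert response_rate(log) == 67.9


@pytest.mark.parametrize(("answered", "expected"), [(40, 100.0), (0, 0.0)])
def test_response_rate_bounds(answered, expected):
    assert response_rate(make_prompt_log(40, answered)) == expected


def test_response_rate_undefined_without_prompts():
    with pytest.raises(UndefinedRateError):
        response_rate(make_prompt_log(10, 5), categories={"educational"})
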