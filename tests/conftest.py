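"""Shared fixtures: a small cohort, a baseline device export, message logs."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gdmtext import LogEntry, Mealtimes, Participant, load_catalog

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def catalog():
    return load_catalog()


@pytest.fixture()
def participant():
    return Participant(
        participant_id="P01",
        enrolled_at=datetime(2021, 6, 1, 5, 0),
        mealtimes=Mealtimes(time(8, 0), time(12, 30), time(19, 0)),
        weekly_message_day=2,
        weekly_message_time=time(10, 0),
    )


def make_participant(pid: str, *, enrolled=datetime(2021, 6, 1, 5, 0),
                     breakfast=time(8, 0), lunch=time(12, 30), dinner=time(19, 0),
                     recommended=4, program_days=14) -> Participant:
    return Participant(
        participant_id=pid,
        enrolled_at=enrolled,
        mealtimes=Mealtimes(breakfast, lunch, dinner),
        recommended_checks_per_day=recommended,
        program_days=program_days,
    )


@pytest.fixture()
def baseline_cohort():
    """Roster + device export whose pre-week totals are 222/238 checks.

    Nine participants monitored over the 7 days before enrollment on
    2021-06-08: eight are recommended 4 checks/day (224 recommended) and
    one is recommended 2/day (14 recommended), totalling 238.  One of the
    4/day participants misses 16 checks (performs 12), so 222 checks are
    performed overall.
    """
    enrolled = datetime(2021, 6, 8, 5, 0)
    roster, rows = [], []
    slot_times = [time(7, 30), time(9, 5), time(13, 35), time(20, 10)]

    def add_day(pid: str, day: date, n_checks: int) -> None:
        for t in slot_times[:n_checks]:
            rows.append((pid, datetime.combine(day, t), 100))

    for i in range(8):
        pid = f"B{i + 1:02d}"
        roster.append(make_participant(pid, enrolled=enrolled))
        per_day = [4] * 7 if i else [0, 0, 0, 0, 4, 4, 4]  # B01 misses 16
        for d, n in enumerate(per_day):
            add_day(pid, enrolled.date() - timedelta(days=7 - d), n)
    pid = "B09"
    roster.append(make_participant(pid, enrolled=enrolled, recommended=2))
    for d in range(7):
        add_day(pid, enrolled.date() - timedelta(days=7 - d), 2)

    device = pd.DataFrame(rows, columns=["participant_id", "datetime", "glucose_mgdl"])
    return roster, device


def make_prompt_log(n_prompts: int, n_answered: int) -> list[LogEntry]:
    """A message log of reminder prompts, the first ``n_answered`` replied to."""
    base = datetime(2021, 6, 2, 7, 30)
    log = []
    seq = 0
    for i in range(n_prompts):
        seq += 1
        log.append(
            LogEntry(seq, base + timedelta(hours=i), "out", f"P{i % 10:02d}",
                     "reminder", "fasting", "check your number", None)
        )
        if i < n_answered:
            seq += 1
            log.append(
                LogEntry(seq, base + timedelta(hours=i, minutes=9), "in",
                         f"P{i % 10:02d}", "glucose_value", None, "88", seq - 1)
            )
    return log
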