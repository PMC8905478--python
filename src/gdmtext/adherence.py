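"""Self-monitoring adherence from glucometer exports, and the pre/during test.

Adherence is the number of glucose checks performed divided by the number
recommended by the clinician, expressed as a percent and capped at 100%:
checking more often than recommended still counts as full adherence.  The
cap is applied per calendar day by default (a binge day cannot mask missed
days); an aggregate-level cap is available via ``cap="aggregate"``.

Repeat fingersticks within five minutes (a failed strip, an immediate
retest) collapse to a single check event.

The pre-enrollment week is compared with the during-program fortnight with
a two-sample Wilcoxon rank-sum test: exact enumeration of the rank-sum
distribution when both groups have at most 10 tie-free observations, and a
tie-corrected normal approximation with continuity correction otherwise.
Shapiro–Wilk normality probabilities and medians with 25th–75th IQRs are
reported alongside; differences are called significant below P = .05.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date, datetime, timedelta
from math import comb, sqrt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scheduler import Participant

__all__ = [
    "AdherenceSummary",
    "RankTestResult",
    "UndefinedAdherenceError",
    "read_device_export",
    "write_device_export",
    "count_checks",
    "daily_check_counts",
    "adherence_pct",
    "cohort_adherence",
    "rank_sum_test",
    "compare_periods",
    "analyze_cohort",
    "write_report",
]

#: Readings closer together than this merge into one check event.
DEDUP_WINDOW = timedelta(minutes=5)

ALPHA = 0.05


class UndefinedAdherenceError(ZeroDivisionError):
    pass


@dataclasses.dataclass(frozen=True)
class AdherenceSummary:
    participant_id: str
    period: str  # "pre" | "during"
    performed: int  # capped count of checks credited
    recommended: int
    pct: int  # rounded percent for reporting
    fraction: float  # raw capped fraction, retained for statistics


@dataclasses.dataclass(frozen=True)
class RankTestResult:
    """Two-sample rank-sum comparison of per-participant adherence."""

    statistic: float  # rank sum W of group 1
    p_value: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: tuple[float, float]
    iqr2: tuple[float, float]
    shapiro_p1: float | None
    shapiro_p2: float | None

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iqr1"] = list(self.iqr1)
        d["iqr2"] = list(self.iqr2)
        d["significant"] = self.significant
        return d


# ---------------------------------------------------------------------------
# Device export

def read_device_export(path: str | Path) -> pd.DataFrame:
    """Read a glucometer CSV export (participant_id, datetime, glucose_mgdl)."""
    df = pd.read_csv(path)
    required = {"participant_id", "datetime", "glucose_mgdl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"device export missing columns: {sorted(missing)}")
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["datetime"] = pd.to_datetime(df["datetime"])
    return df.sort_values(["participant_id", "datetime"], kind="stable").reset_index(
        drop=True
    )


def write_device_export(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["datetime"] = pd.to_datetime(out["datetime"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def _cluster_times(times: Sequence[datetime], window: timedelta) -> list[datetime]:
    """Collapse a sorted time sequence; each cluster keeps its first time."""
    reps: list[datetime] = []
    previous: datetime | None = None
    for t in times:
        if previous is None or t - previous > window:
            reps.append(t)
        previous = t
    return reps


def daily_check_counts(
    records: pd.DataFrame, window: timedelta = DEDUP_WINDOW
) -> dict[tuple[str, date], int]:
    """Deduplicated check events per (participant, local calendar day).

    Clustering runs over the participant's full timeline, so a retest just
    after midnight merges with its predecessor; the cluster is assigned to
    the day of its first reading.
    """
    counts: dict[tuple[str, date], int] = {}
    for pid, group in records.groupby("participant_id", sort=True):
        times = sorted(ts.to_pydatetime() for ts in pd.to_datetime(group["datetime"]))
        for rep in _cluster_times(times, window):
            key = (str(pid), rep.date())
            counts[key] = counts.get(key, 0) + 1
    return counts


def count_checks(
    records: pd.DataFrame,
    participant_id: str,
    day: date,
    window: timedelta = DEDUP_WINDOW,
) -> int:
    """Distinct check events for one participant on one calendar day."""
    mask = records["participant_id"].astype(str) == str(participant_id)
    sub = records.loc[mask]
    times = sorted(
        t
        for t in (ts.to_pydatetime() for ts in pd.to_datetime(sub["datetime"]))
        if t.date() == day
    )
    return len(_cluster_times(times, window))


# ---------------------------------------------------------------------------
# Adherence percentage

def adherence_pct(
    performed_by_day: Mapping[date, int] | Sequence[int],
    recommended_per_day: int,
    period: str,
    participant_id: str = "",
    cap: str = "per_day",
) -> AdherenceSummary:
    """Capped adherence over a period of days.

    ``performed_by_day`` maps each day of the period to its check count (a
    plain sequence of daily counts is also accepted).  With the default
    per-day cap, each day credits at most ``recommended_per_day`` checks;
    with ``cap="aggregate"`` the cap is applied to the period totals only.
    """
    if recommended_per_day < 1:
        raise UndefinedAdherenceError("recommended_per_day must be >= 1")
    counts = (
        list(performed_by_day.values())
        if isinstance(performed_by_day, Mapping)
        else list(performed_by_day)
    )
    if not counts:
        raise UndefinedAdherenceError("period contains no days")
    recommended = recommended_per_day * len(counts)
    if cap == "per_day":
        performed = sum(min(c, recommended_per_day) for c in counts)
    elif cap == "aggregate":
        performed = min(sum(counts), recommended)
    else:
        raise ValueError(f"unknown cap mode {cap!r}")
    fraction = performed / recommended
    return AdherenceSummary(
        participant_id=participant_id,
        period=period,
        performed=performed,
        recommended=recommended,
        pct=int(np.floor(100.0 * fraction + 0.5)),
        fraction=fraction,
    )


def cohort_adherence(summaries: Iterable[AdherenceSummary]) -> tuple[int, int, int]:
    """Pooled (performed, recommended, percent) across participants."""
    summaries = list(summaries)
    performed = sum(s.performed for s in summaries)
    recommended = sum(s.recommended for s in summaries)
    if recommended == 0:
        raise UndefinedAdherenceError("no recommended checks in cohort")
    return performed, recommended, int(np.floor(100.0 * performed / recommended + 0.5))


# ---------------------------------------------------------------------------
# Rank-sum test

def _exact_ranksum_p(w_obs: float, n1: int, n2: int) -> float:
    """Exact two-sided p for the rank sum of group 1 (no ties).

    Counts subsets of {1..N} of size n1 by sum with a dynamic-programming
    recurrence; p = min(1, 2*min(P(W <= w), P(W >= w))).
    """
    N = n1 + n2
    max_w = sum(range(N - n1 + 1, N + 1))
    # f[k][w]: number of k-subsets of {1..r} with rank sum w
    f = [[0] * (max_w + 1) for _ in range(n1 + 1)]
    f[0][0] = 1
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            fk, fk1 = f[k], f[k - 1]
            for w in range(max_w, r - 1, -1):
                fk[w] += fk1[w - r]
    counts = f[n1]
    total = comb(N, n1)
    w = int(round(w_obs))
    p_low = sum(counts[: w + 1]) / total
    p_high = sum(counts[w:]) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Wilcoxon rank-sum statistic W (rank sum of x) and two-sided p.

    Exact when both samples have <= 10 observations and the pooled sample
    is tie-free; otherwise a normal approximation with tie-corrected
    variance and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties and n1 <= 10 and n2 <= 10:
        return w, _exact_ranksum_p(w, n1, n2), "exact"
    N = n1 + n2
    mean = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum()) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var == 0:  # all observations identical
        return w, 1.0, "normal_approx"
    z = max(0.0, abs(w - mean) - 0.5) / sqrt(var)
    p = 2.0 * stats.norm.sf(z)
    return w, min(1.0, p), "normal_approx"


def _shapiro_p(values: np.ndarray) -> float | None:
    if len(values) < 3 or np.ptp(values) == 0:
        return None
    return float(stats.shapiro(values).pvalue)


def compare_periods(
    pre: Sequence[float], during: Sequence[float], paired: bool = False
) -> RankTestResult:
    """Compare per-participant adherence fractions pre vs during.

    The default is the unpaired rank-sum test (the named analysis); a
    paired Wilcoxon signed-rank variant is available with ``paired=True``
    for sensitivity analyses, since pre and during really are measurements
    on the same women.
    """
    x = np.asarray(pre, dtype=float)
    y = np.asarray(during, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal-length groups")
        if np.all(x == y):
            stat, p, method = 0.0, 1.0, "signed_rank"
        else:
            res = stats.wilcoxon(x, y)
            stat, p, method = float(res.statistic), float(res.pvalue), "signed_rank"
    else:
        stat, p, method = rank_sum_test(x, y)
    q1 = np.percentile(x, [25, 75])
    q2 = np.percentile(y, [25, 75])
    return RankTestResult(
        statistic=stat,
        p_value=p,
        method=method,
        n1=len(x),
        n2=len(y),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        iqr1=(float(q1[0]), float(q1[1])),
        iqr2=(float(q2[0]), float(q2[1])),
        shapiro_p1=_shapiro_p(x),
        shapiro_p2=_shapiro_p(y),
    )


# ---------------------------------------------------------------------------
# Cohort pipeline

def _window_days(start: date, n_days: int) -> list[date]:
    return [start + timedelta(days=i) for i in range(n_days)]


def analyze_cohort(
    records: pd.DataFrame,
    roster: Sequence[Participant],
    pre_days: int = 7,
    cap: str = "per_day",
    dedup_window: timedelta = DEDUP_WINDOW,
) -> tuple[list[AdherenceSummary], RankTestResult | None]:
    """Per-participant pre/during adherence plus the rank-sum comparison.

    The pre period is the ``pre_days`` calendar days before enrollment; the
    during period is ``program_days`` days starting the day after
    enrollment (messages begin after a 24-hour delay).  Participants with
    no device data in the pre period are excluded from the statistical
    comparison — they were not yet self-monitoring — but still get a
    during-period summary.
    """
    counts = daily_check_counts(records, dedup_window) if len(records) else {}
    summaries: list[AdherenceSummary] = []
    pre_fracs: list[float] = []
    during_fracs: list[float] = []
    for p in roster:
        enroll_day = p.enrolled_at.date()
        pre_window = _window_days(enroll_day - timedelta(days=pre_days), pre_days)
        during_window = _window_days(enroll_day + timedelta(days=1), p.program_days)
        pre_counts = {d: counts.get((p.participant_id, d), 0) for d in pre_window}
        during_counts = {d: counts.get((p.participant_id, d), 0) for d in during_window}
        pre_summary = adherence_pct(
            pre_counts, p.recommended_checks_per_day, "pre", p.participant_id, cap
        )
        during_summary = adherence_pct(
            during_counts, p.recommended_checks_per_day, "during", p.participant_id, cap
        )
        summaries.extend([pre_summary, during_summary])
        if sum(pre_counts.values()) > 0:
            pre_fracs.append(pre_summary.fraction)
            during_fracs.append(during_summary.fraction)
    result = (
        compare_periods(pre_fracs, during_fracs)
        if len(pre_fracs) >= 2
        else None
    )
    return summaries, result


def write_report(
    summaries: Sequence[AdherenceSummary],
    result: RankTestResult | None,
    csv_path: str | Path,
    json_path: str | Path,
) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        csv_path, index=False
    )
    payload = result.to_dict() if result is not None else None
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
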