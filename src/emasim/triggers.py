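"""Trigger simulation: sync cadence, scheduling constraints, prompt lifecycle.

The wearable uploads data only at syncs (nominally every 15 minutes), so an
event-based survey can fire only at a sync, and only if a qualifying bout
ended within the rule's *backwards span* before that sync.  The scheduler
then applies the protocol constraints: a per-kind refractory interval
(90 min), per-window caps for sedentary surveys (2 in 08:00–14:00 and 2 in
14:00–20:00), per-kind daily caps (3 for walking and running), and a joint
daily cap on all event-based surveys (10).

Scheduling is greedy and chronological — the earliest eligible sync wins,
mirroring a real-time server.  Ties between kinds at one sync resolve in the
order sedentary → walking → running.  The refractory interval is enforced
across the whole timeline (it does not reset at midnight); caps reset at
midnight.  A bout consumed by a trigger never re-fires.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

KIND_ORDER = ("sedentary", "walking", "running")

TRIGGER_COLUMNS = ["fire_time", "kind", "bout_end", "delay_min"]

#: The seven daily time-based survey frames (inclusive minute bounds).
TIME_BASED_WINDOWS: tuple[tuple[str, str, str], ...] = (
    ("morning", "06:00", "09:45"),
    ("daily_1", "10:15", "11:45"),
    ("daily_2", "12:15", "13:45"),
    ("daily_3", "14:15", "15:45"),
    ("daily_4", "16:15", "17:45"),
    ("daily_5", "18:15", "19:45"),
    ("evening", "20:15", "22:00"),
)


def _parse_hhmm(s: str) -> int:
    h, m = s.split(":")
    return int(h) * 60 + int(m)


class SyncModel(BaseModel):
    """Cadence at which the tracker uploads data (bounds trigger latency)."""

    period_min: int = 15
    offset_min: int = 0
    mode: Literal["regular", "jittered"] = "regular"
    jitter_sd_min: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "SyncModel":
        if self.period_min < 1:
            raise ValueError("period_min must be >= 1")
        if not 0 <= self.offset_min < self.period_min:
            raise ValueError("offset_min must lie in [0, period_min)")
        return self


class WindowCap(BaseModel):
    """A daily clock window with a cap on triggers fired inside it."""

    start: str  # "HH:MM", inclusive
    end: str    # "HH:MM", exclusive
    cap: int

    @property
    def start_min(self) -> int:
        return _parse_hhmm(self.start)

    @property
    def end_min(self) -> int:
        return _parse_hhmm(self.end)

    @model_validator(mode="after")
    def _check(self) -> "WindowCap":
        if self.cap < 0:
            raise ValueError("cap must be >= 0")
        if self.start_min >= self.end_min:
            raise ValueError("window start must precede end")
        return self


class ScheduleConstraints(BaseModel):
    """Per-kind scheduling constraints for event-based surveys."""

    backwards_span_min: int
    min_interval_min: int = 90
    windows: list[WindowCap] = []
    daily_cap: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ScheduleConstraints":
        if self.backwards_span_min < 1:
            raise ValueError("backwards_span_min must be >= 1")
        if self.min_interval_min < 0:
            raise ValueError("min_interval_min must be >= 0")
        spans = sorted((w.start_min, w.end_min) for w in self.windows)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("constraint windows must not overlap")
        return self

    def window_index(self, minute_of_day: int) -> Optional[int]:
        for i, w in enumerate(self.windows):
            if w.start_min <= minute_of_day < w.end_min:
                return i
        return None


class PromptLifecycle(BaseModel):
    """Reminder offsets and expiry for a prompted survey, in minutes."""

    reminder_offsets_min: tuple[int, ...] = (3, 6, 7)
    expiry_min: float = 8.0

    @model_validator(mode="after")
    def _check(self) -> "PromptLifecycle":
        if any(r >= self.expiry_min for r in self.reminder_offsets_min):
            raise ValueError("reminders must fall strictly before expiry")
        return self


def sync_times(
    sync: SyncModel, date: dt.date, rng: np.random.Generator | None = None
) -> pd.DatetimeIndex:
    """Sync instants within ``date``; jittered mode needs an ``rng``."""
    day_start = pd.Timestamp(date)
    offsets = np.arange(sync.offset_min, 1440, sync.period_min, dtype=float)
    if sync.mode == "jittered":
        if rng is None:
            raise ValueError("jittered sync model needs an rng")
        offsets = offsets + rng.normal(0.0, sync.jitter_sd_min, size=len(offsets))
        offsets = np.sort(np.clip(offsets, 0.0, 1439.99))
    return day_start + pd.to_timedelta(offsets, unit="m")


def simulate_event_triggers(
    bouts_by_kind: dict[str, pd.DataFrame],
    sync: SyncModel,
    constraints: dict[str, ScheduleConstraints],
    dates: Sequence[dt.date],
    total_daily_cap: Optional[int] = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replay the trigger engine over ``dates``.

    At each sync ``t`` and for each kind (sedentary → walking → running), the
    most recent unconsumed bout whose end minute lies in
    ``[t − backwards_span, t)`` fires a trigger iff the refractory interval,
    the window / daily / total caps, and the clock-window restriction all
    allow it.  At most one trigger per kind per sync; a bout fires at most
    once.  Returns a DataFrame with ``fire_time``, ``kind``, ``bout_end`` and
    ``delay_min`` (minutes from the end of the bout's last minute to the
    fire time).
    """
    state = {}
    for kind, bouts in bouts_by_kind.items():
        if kind not in constraints:
            raise ValueError(f"no constraints supplied for kind {kind!r}")
        ends = np.sort(bouts["end_minute"].to_numpy().astype("datetime64[m]"))
        state[kind] = {"ends": ends, "consumed": np.zeros(len(ends), bool)}

    last_fire: dict[str, pd.Timestamp | None] = {k: None for k in bouts_by_kind}
    records = []
    for date in dates:
        daily_count = {k: 0 for k in bouts_by_kind}
        window_count: dict[tuple[str, int], int] = {}
        total_today = 0
        for t in sync_times(sync, date, rng):
            t64 = np.datetime64(t.floor("min"), "m")
            for kind in KIND_ORDER:
                if kind not in bouts_by_kind:
                    continue
                c = constraints[kind]
                ends, consumed = state[kind]["ends"], state[kind]["consumed"]
                lo = np.searchsorted(ends, t64 - np.timedelta64(c.backwards_span_min, "m"))
                hi = np.searchsorted(ends, t64)  # end < t
                cand = None
                for i in range(hi - 1, lo - 1, -1):  # most recent first
                    if not consumed[i]:
                        cand = i
                        break
                if cand is None:
                    continue
                minute_of_day = t.hour * 60 + t.minute
                widx = None
                if c.windows:
                    widx = c.window_index(minute_of_day)
                    if widx is None:
                        continue
                    if window_count.get((kind, widx), 0) >= c.windows[widx].cap:
                        continue
                if c.daily_cap is not None and daily_count[kind] >= c.daily_cap:
                    continue
                if total_daily_cap is not None and total_today >= total_daily_cap:
                    continue
                if (
                    last_fire[kind] is not None
                    and (t - last_fire[kind]) < pd.Timedelta(minutes=c.min_interval_min)
                ):
                    continue
                bout_end = pd.Timestamp(ends[cand])
                records.append(
                    {
                        "fire_time": t,
                        "kind": kind,
                        "bout_end": bout_end,
                        "delay_min": (t - bout_end - pd.Timedelta(minutes=1))
                        / pd.Timedelta(minutes=1),
                    }
                )
                consumed[cand] = True
                last_fire[kind] = t
                daily_count[kind] += 1
                total_today += 1
                if widx is not None:
                    window_count[(kind, widx)] = window_count.get((kind, widx), 0) + 1
    return pd.DataFrame(records, columns=TRIGGER_COLUMNS)


def schedule_time_based(
    study_days: Sequence[dt.date],
    rng: np.random.Generator,
    windows: Sequence[tuple[str, str, str]] = TIME_BASED_WINDOWS,
) -> pd.DataFrame:
    """Pre-draw one uniformly random prompt minute per window per day.

    The whole study is drawn up-front (the live platform pre-schedules
    time-based surveys so they fire even without connectivity).  Returns a
    DataFrame with ``date``, ``survey_type`` and ``prompt_time``.
    """
    rows = []
    for date in study_days:
        for label, start, end in windows:
            lo, hi = _parse_hhmm(start), _parse_hhmm(end)
            minute = int(rng.integers(lo, hi + 1))  # inclusive bounds
            rows.append(
                {
                    "date": date,
                    "survey_type": label,
                    "prompt_time": pd.Timestamp(date) + pd.Timedelta(minutes=minute),
                }
            )
    return pd.DataFrame(rows)


def apply_lifecycle(
    prompt_time: pd.Timestamp,
    lifecycle: PromptLifecycle,
    latency_s: Optional[float],
    completion_s: Optional[float] = None,
) -> dict:
    """Walk one prompt through reminders and expiry.

    ``latency_s`` is the would-be response start delay (None = never opened).
    A start at or after expiry is rejected as unanswered.  Reminders fire at
    their offsets while the prompt is still unanswered.
    """
    expiry_s = lifecycle.expiry_min * 60.0
    answered = latency_s is not None and latency_s < expiry_s
    if answered:
        reminders = [r for r in lifecycle.reminder_offsets_min if r * 60.0 < latency_s]
    else:
        reminders = list(lifecycle.reminder_offsets_min)
    return {
        "prompt_time": prompt_time,
        "answered": answered,
        "start_time": prompt_time + pd.Timedelta(seconds=latency_s) if answered else None,
        "latency_s": latency_s if answered else None,
        "completion_s": completion_s if answered else None,
        "reminder_times": [prompt_time + pd.Timedelta(minutes=r) for r in reminders],
        "expiry_time": None if answered else prompt_time + pd.Timedelta(minutes=lifecycle.expiry_min),
    }
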