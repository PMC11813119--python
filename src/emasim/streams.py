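"""Minute-epoch wearable streams: data model, CSV I/O, wear-time accounting.

A stream is a per-participant sequence of minute epochs, each carrying a step
count and the number of heart-rate samples the tracker logged during that
minute.  Heart-rate presence is the wear proxy: a minute is "worn" iff at
least one heart-rate sample was recorded in it.  A *valid day* has at least
600 worn minutes (10 hours); trigger-optimisation simulations are restricted
to participants with a required number of valid days.

Times are local civil times at minute resolution; streams are assumed
DST-free.  A minute epoch covers the half-open interval [t, t+60 s) and
belongs to the civil date of its start.  Minutes missing from a stream are
treated as not worn (and zero steps) for wear accounting, but they are
distinguishable from recorded zeros because they are simply absent from the
epoch table.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("emasim")

#: Minimum worn minutes for a day to count as valid.
VALID_DAY_MINUTES = 600

#: Columns of the minute-epoch CSV interchange format.
MINUTE_CSV_COLUMNS = ["participant_id", "site", "timestamp", "steps", "hr_samples"]

SITES = ("CZ", "DE", "FR", "IE")


class StreamFormatError(ValueError):
    """The file-level schema is wrong (missing columns, unreadable header)."""


class StreamRowError(ValueError):
    """One or more data rows are malformed; the message lists row numbers."""


@dataclass
class ParticipantStream:
    """One participant's ordered minute-epoch series.

    ``epochs`` is a DataFrame with columns ``minute_start`` (datetime64,
    minute-aligned), ``steps`` (int) and ``hr_samples`` (int), strictly
    increasing in ``minute_start`` with no duplicate minutes; gaps are
    allowed and mean "not recorded".
    """

    participant_id: str
    site: str
    epochs: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = {"minute_start", "steps", "hr_samples"} - set(self.epochs.columns)
        if missing:
            raise StreamFormatError(f"epochs missing columns: {sorted(missing)}")
        ts = self.epochs["minute_start"]
        if not pd.api.types.is_datetime64_any_dtype(ts):
            raise StreamFormatError("minute_start must be datetime64")
        if len(ts) and ((ts.dt.second != 0).any() or (ts.dt.microsecond != 0).any()):
            raise ValueError("minute_start values must be aligned to whole minutes")
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("epochs must be sorted by minute_start")
        if ts.duplicated().any():
            raise ValueError("duplicate minutes in stream")
        if (self.epochs["steps"] < 0).any() or (self.epochs["hr_samples"] < 0).any():
            raise ValueError("steps and hr_samples must be non-negative")

    @property
    def study_days(self) -> list[dt.date]:
        """Ordered civil dates covered by the stream."""
        return sorted(self.epochs["minute_start"].dt.date.unique())

    def day_epochs(self, date: dt.date) -> pd.DataFrame:
        mask = self.epochs["minute_start"].dt.date == date
        return self.epochs.loc[mask]


@dataclass(frozen=True)
class DaySummary:
    date: dt.date
    wear_minutes: int
    total_steps: int
    is_valid: bool


def wear_minutes(stream: ParticipantStream, date: dt.date) -> int:
    """Worn minutes on ``date``: recorded minutes with ≥1 heart-rate sample."""
    if date not in stream.study_days:
        raise ValueError(f"{date} not in study days of {stream.participant_id}")
    day = stream.day_epochs(date)
    return int((day["hr_samples"] >= 1).sum())


def is_valid_day(
    stream: ParticipantStream, date: dt.date, threshold: int = VALID_DAY_MINUTES
) -> bool:
    """True iff the day has at least ``threshold`` worn minutes (default 600)."""
    return wear_minutes(stream, date) >= threshold


def summarise_days(
    stream: ParticipantStream, threshold: int = VALID_DAY_MINUTES
) -> list[DaySummary]:
    out = []
    for date in stream.study_days:
        day = stream.day_epochs(date)
        wm = int((day["hr_samples"] >= 1).sum())
        out.append(
            DaySummary(
                date=date,
                wear_minutes=wm,
                total_steps=int(day["steps"].sum()),
                is_valid=wm >= threshold,
            )
        )
    return out


def filter_simulation_cohort(
    streams: Iterable[ParticipantStream],
    required_days: int,
    threshold: int = VALID_DAY_MINUTES,
) -> tuple[list[ParticipantStream], pd.DataFrame]:
    """Keep streams with at least ``required_days`` valid days.

    Returns ``(kept, exclusion_log)`` where the log has one row per excluded
    participant with their valid-day count.  Mirrors the study's restriction
    of the trigger simulations to participants with a full week of valid wear.
    """
    if required_days < 1:
        raise ValueError("required_days must be >= 1")
    kept: list[ParticipantStream] = []
    excluded: list[dict] = []
    for s in streams:
        n_valid = sum(is_valid_day(s, d, threshold) for d in s.study_days)
        if n_valid >= required_days:
            kept.append(s)
        else:
            excluded.append({"participant_id": s.participant_id, "n_valid_days": n_valid})
            logger.info(
                "excluding %s: %d valid day(s) < %d required",
                s.participant_id, n_valid, required_days,
            )
    log = pd.DataFrame(excluded, columns=["participant_id", "n_valid_days"])
    return kept, log


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_minute_csv(path: str | Path) -> list[ParticipantStream]:
    """Read the minute-epoch CSV (one row per participant-minute).

    Schema: ``participant_id,site,timestamp,steps,hr_samples`` with ISO-8601
    minute-resolution timestamps.  Raises :class:`StreamFormatError` for a bad
    header and :class:`StreamRowError` naming offending rows (2-based, header
    = row 1) for non-integer counts or duplicate (participant, minute) pairs.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MINUTE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return []
    problems: list[str] = []
    for col in ("steps", "hr_samples"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.round())
        for idx in df.index[bad]:
            problems.append(f"row {idx + 2}: non-integer {col} {df.at[idx, col]!r}")
        df[col] = parsed
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    for idx in df.index[ts.isna()]:
        problems.append(f"row {idx + 2}: unparseable timestamp {df.at[idx, 'timestamp']!r}")
    df["timestamp"] = ts
    dup = df.duplicated(subset=["participant_id", "timestamp"], keep=False)
    if dup.any():
        for (pid, t), grp in df[dup].groupby(["participant_id", "timestamp"]):
            rows = ", ".join(str(i + 2) for i in grp.index)
            problems.append(f"duplicate minute {t} for {pid} at rows {rows}")
    if problems:
        raise StreamRowError(f"{path}: " + "; ".join(problems))

    streams = []
    for pid, grp in df.groupby("participant_id", sort=True):
        site = grp["site"].iloc[0]
        epochs = (
            grp.rename(columns={"timestamp": "minute_start"})
            [["minute_start", "steps", "hr_samples"]]
            .astype({"steps": np.int64, "hr_samples": np.int64})
            .sort_values("minute_start")
            .reset_index(drop=True)
        )
        streams.append(ParticipantStream(str(pid), str(site), epochs))
    return streams


def write_minute_csv(streams: Sequence[ParticipantStream], path: str | Path) -> None:
    """Write streams in the minute-epoch CSV schema (round-trips with reader)."""
    frames = []
    for s in streams:
        f = s.epochs.copy()
        f.insert(0, "participant_id", s.participant_id)
        f.insert(1, "site", s.site)
        frames.append(f.rename(columns={"minute_start": "timestamp"}))
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    else:
        out = pd.DataFrame(columns=MINUTE_CSV_COLUMNS)
    out.to_csv(path, index=False, columns=MINUTE_CSV_COLUMNS)
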