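"""Protocol parameter sweeps: expected triggers/day under alternative rules.

Re-runs the trigger simulation over a grid of rule variants on a cohort of
minute-epoch streams and summarises triggers per day as the median (IQR) of
participants' daily means — the computational twin of the study-style
optimisation tables.  The shipped grids vary one parameter at a time from
the original protocol (backwards span, outlier allowance/direction, event
duration) plus the combined "Optimal" row.

Absolute trigger counts depend entirely on the cohort's activity patterns;
on synthetic cohorts the sweep reproduces the grids' structure and the
orderings that follow from relaxing rules, not any particular field value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import EventRule, find_bouts
from .streams import VALID_DAY_MINUTES, ParticipantStream, is_valid_day
from .triggers import ScheduleConstraints, SyncModel, WindowCap, simulate_event_triggers

SEDENTARY_WINDOWS = [
    WindowCap(start="08:00", end="14:00", cap=2),
    WindowCap(start="14:00", end="20:00", cap=2),
]


@dataclass(frozen=True)
class SweepSetting:
    """One labelled row of a sweep grid."""

    label: str
    rule: EventRule
    constraints: ScheduleConstraints


@dataclass
class SweepSummary:
    """Median (IQR) of participants' mean triggers/day for one setting."""

    label: str
    rule: EventRule
    constraints: ScheduleConstraints
    per_participant_daily_mean: pd.Series
    median: float
    q1: float
    q3: float


def _sed(label: str, duration: int, outliers: int, span: int) -> SweepSetting:
    return SweepSetting(
        label=label,
        rule=EventRule(
            kind="sedentary",
            duration_min=duration,
            step_low=0,
            step_high=0,
            outlier_allowance=outliers,
            outlier_direction="above_high" if outliers else "none",
            require_hr_each_minute=True,
        ),
        constraints=ScheduleConstraints(
            backwards_span_min=span,
            min_interval_min=90,
            windows=SEDENTARY_WINDOWS,
            daily_cap=4,
        ),
    )


def _walk(label: str, duration: int, direction: str, span: int) -> SweepSetting:
    return SweepSetting(
        label=label,
        rule=EventRule(
            kind="walking",
            duration_min=duration,
            step_low=60,
            step_high=139,
            outlier_allowance=2,
            outlier_direction=direction,
            require_hr_each_minute=False,
        ),
        constraints=ScheduleConstraints(
            backwards_span_min=span, min_interval_min=90, windows=[], daily_cap=3
        ),
    )


def sedentary_sweep_settings() -> list[SweepSetting]:
    """The sedentary grid: one-parameter relaxations of the 30-min rule."""
    return [
        _sed("Original", 30, 0, 1),
        _sed("Backwards 17", 30, 0, 17),
        _sed("Outlier 1", 30, 1, 1),
        _sed("Duration 20", 20, 0, 1),
        _sed("Optimal", 20, 0, 1),  # identical to "Duration 20"
    ]


def walking_sweep_settings() -> list[SweepSetting]:
    """The walking grid: relaxations of the 10-min 60–139 steps/min rule."""
    return [
        _walk("Original", 10, "above_high", 2),
        _walk("Backwards 17", 10, "above_high", 17),
        _walk("Outliers below", 10, "below_low", 2),
        _walk("Duration 5", 5, "above_high", 2),
        _walk("Optimal", 5, "below_low", 17),
    ]


def quantile_summary(values) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation (type-7 quantiles)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("quantile_summary needs a non-empty collection")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def run_sweep(
    cohort: list[ParticipantStream],
    settings: list[SweepSetting],
    sync: SyncModel | None = None,
    valid_day_threshold: int = VALID_DAY_MINUTES,
) -> list[SweepSummary]:
    """Evaluate every setting on every participant.

    For each setting: detect bouts on the full stream, simulate triggers
    over the participant's study days, count triggers landing on valid days
    and divide by the number of valid days; then take the median and IQR of
    those per-participant means.  The cohort should already be restricted to
    participants with the required number of valid days
    (:func:`emasim.streams.filter_simulation_cohort`).
    """
    if not cohort:
        raise ValueError("run_sweep needs a non-empty cohort")
    sync = sync or SyncModel()
    valid_days = {
        s.participant_id: [d for d in s.study_days if is_valid_day(s, d, valid_day_threshold)]
        for s in cohort
    }
    summaries = []
    for setting in settings:
        means = {}
        for stream in cohort:
            days = valid_days[stream.participant_id]
            if not days:
                continue
            bouts = find_bouts(stream.epochs, setting.rule)
            trig = simulate_event_triggers(
                {setting.rule.kind: bouts},
                sync,
                {setting.rule.kind: setting.constraints},
                stream.study_days,
                total_daily_cap=None,  # single-kind sweep; joint cap not in play
            )
            if len(trig):
                on_valid = trig["fire_time"].dt.date.isin(days).sum()
            else:
                on_valid = 0
            means[stream.participant_id] = on_valid / len(days)
        series = pd.Series(means, name=setting.label)
        med, q1, q3 = quantile_summary(series.to_numpy())
        summaries.append(
            SweepSummary(
                label=setting.label,
                rule=setting.rule,
                constraints=setting.constraints,
                per_participant_daily_mean=series,
                median=med,
                q1=q1,
                q3=q3,
            )
        )
    return summaries


def sweep_table(summaries: list[SweepSummary]) -> pd.DataFrame:
    """Render summaries in the optimisation-table layout."""
    rows = []
    for s in summaries:
        r = s.rule
        if r.step_low == r.step_high == 0:
            threshold = "= 0"
        elif r.step_high is None:
            threshold = f">= {r.step_low}"
        else:
            threshold = f"{r.step_low} to {r.step_high}"
        if r.outlier_allowance == 0:
            outliers = "0"
        else:
            sign = ">" if r.outlier_direction == "above_high" else "<"
            bound = r.step_high if r.outlier_direction == "above_high" else r.step_low
            outliers = f"{r.outlier_allowance} ({sign} {bound} steps)"
        rows.append(
            {
                "Setting": s.label,
                "Event duration (min)": r.duration_min,
                "Threshold (steps)": threshold,
                "Outliers (min)": outliers,
                "Backwards (min)": s.constraints.backwards_span_min,
                "Triggers median (IQR)": f"{s.median:.2f} ({s.q1:.2f}-{s.q3:.2f})",
            }
        )
    return pd.DataFrame(rows)
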