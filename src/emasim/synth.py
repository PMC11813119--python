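"""Synthetic cohort generator: activity streams, prompt responses, meal reports.

Emulates a free-living adult cohort wearing a wrist tracker around the clock:
daily wear time ≈ 1,357 ± 124 minutes and daily steps ≈ 11,189 ± 2,881, with
a nightly sleep window of worn zero-step minutes, sedentary/walking/running
bout structure in waking time, and occasional non-wear gaps.  Prompt-response
behaviour and meal/snack/drink reporting follow the declining daily trends a
week-long protocol induces (habituation): the response probability falls
≈1.66 percentage points per day, survey completion time ≈1.62 s per day, and
the number of eating reports ≈0.17 per day.

Every generator takes a ``numpy.random.Generator`` and is bit-reproducible
under a fixed seed.  These are study-condition emulators, not physiological
models: step counts within a bout are i.i.d. around a typical cadence, and
there is no circadian structure beyond the sleep window.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .streams import SITES, ParticipantStream
from .triggers import PromptLifecycle

MEAL_CATEGORIES = ("breakfast", "lunch", "dinner", "snack", "drink")

DEFAULT_START_DATE = dt.date(2023, 3, 6)


class ActivityProfile(BaseModel):
    """Targets and bout mix for one participant-day of tracker data.

    Daily non-wear is drawn from a gamma distribution with mean
    ``1440 − mean_wear_minutes`` and sd ``sd_wear_minutes`` (right-skewed:
    most days near-full wear, occasional long recharge gaps, and no
    truncation bias at the 1440-minute ceiling) and placed as gaps in waking
    time.  Steps are composed from walking/running bouts plus light-activity
    filler minutes (1–59 steps) topped up to a daily target drawn from
    N(mean_daily_steps, sd_daily_steps).
    """

    sleep_start: str = "23:00"
    sleep_end: str = "07:00"
    mean_wear_minutes: float = 1357.0
    sd_wear_minutes: float = 124.0
    mean_daily_steps: float = 11189.0
    sd_daily_steps: float = 2881.0
    walking_bouts_per_day: float = 3.0
    walking_dur_shape: float = 2.0
    walking_dur_scale_min: float = 5.0
    walking_steps_mean: float = 100.0
    walking_steps_sd: float = 15.0
    running_bouts_per_day: float = 0.4
    running_dur_shape: float = 2.0
    running_dur_scale_min: float = 4.0
    running_steps_mean: float = 160.0
    running_steps_sd: float = 10.0
    max_nonwear_gaps: int = 3
    hr_samples_mean: float = 4.0


class BehaviourModel(BaseModel):
    """Prompt-response and eating-report behaviour over the study week."""

    base_response_rate: float = 0.55
    daily_response_slope: float = -0.0166  # probability per day
    latency_median_s: float = 127.0
    latency_log_sd: float = 0.6
    completion_mean_s: float = 72.0
    completion_sd_s: float = 15.0
    completion_daily_slope_s: float = -1.62
    completion_min_s: float = 10.0
    # mean reports per participant-day by category
    meal_rates_self: dict[str, float] = {
        "breakfast": 0.80, "lunch": 0.75, "dinner": 0.60, "snack": 0.75, "drink": 1.10,
    }
    meal_rates_prompted: dict[str, float] = {
        "breakfast": 0.15, "lunch": 0.35, "dinner": 0.20, "snack": 0.40, "drink": 0.30,
    }
    meal_daily_slope: float = -0.17  # total reports per day, split across categories


def _hhmm_to_min(s: str) -> int:
    h, m = s.split(":")
    return int(h) * 60 + int(m)


def _sleep_mask(profile: ActivityProfile) -> np.ndarray:
    start = _hhmm_to_min(profile.sleep_start)
    end = _hhmm_to_min(profile.sleep_end)
    minutes = np.arange(1440)
    if start <= end:
        return (minutes >= start) & (minutes < end)
    return (minutes >= start) | (minutes < end)


def _place_blocks(
    free: np.ndarray, durations: Sequence[int], rng: np.random.Generator
) -> list[np.ndarray]:
    """Place non-overlapping blocks of given durations on free minutes."""
    placed = []
    free = free.copy()
    for dur in durations:
        candidates = np.flatnonzero(free)
        if len(candidates) == 0:
            break
        ok_starts = [
            s for s in candidates
            if s + dur <= 1440 and free[s : s + dur].all()
        ]
        if not ok_starts:
            continue
        start = int(rng.choice(ok_starts))
        block = np.arange(start, start + dur)
        free[block] = False
        placed.append(block)
    return placed


def generate_day(
    profile: ActivityProfile, rng: np.random.Generator, date: dt.date = DEFAULT_START_DATE
) -> pd.DataFrame:
    """One full synthetic day: 1440 minute epochs.

    Sleep-window minutes are worn with zero steps; non-wear gaps (hr = 0,
    steps = 0) land only in waking time; walking/running bouts are placed as
    contiguous blocks; remaining waking worn minutes receive light-activity
    steps until the daily step target is met.
    """
    if not 0 <= profile.mean_wear_minutes <= 1440:
        raise ValueError("mean_wear_minutes must lie in [0, 1440]")
    sleep = _sleep_mask(profile)
    waking = ~sleep

    # --- wear ---
    mean_nonwear = 1440.0 - profile.mean_wear_minutes
    sd = profile.sd_wear_minutes
    if mean_nonwear <= 0:
        nonwear_total = 0
    elif sd <= 0:
        nonwear_total = int(round(mean_nonwear))
    else:
        shape = (mean_nonwear / sd) ** 2
        nonwear_total = int(round(rng.gamma(shape, sd**2 / mean_nonwear)))
    nonwear_total = min(nonwear_total, int(waking.sum()))
    worn = np.ones(1440, bool)
    if nonwear_total > 0:
        n_gaps = min(int(rng.integers(1, profile.max_nonwear_gaps + 1)), nonwear_total)
        cuts = np.sort(rng.choice(np.arange(1, nonwear_total), size=n_gaps - 1, replace=False)) if n_gaps > 1 else np.array([], int)
        gap_durs = np.diff(np.concatenate([[0], cuts, [nonwear_total]])).astype(int)
        for block in _place_blocks(waking.copy(), [int(g) for g in gap_durs if g > 0], rng):
            worn[block] = False
        # if blocks could not all be placed, trim by marking remaining shortfall
        shortfall = nonwear_total - (~worn).sum()
        if shortfall > 0:
            free = np.flatnonzero(waking & worn)
            worn[rng.choice(free, size=shortfall, replace=False)] = False

    # --- steps ---
    steps = np.zeros(1440, dtype=np.int64)
    step_target = rng.normal(profile.mean_daily_steps, profile.sd_daily_steps)
    step_target = max(0.0, step_target)
    free = waking & worn
    n_walk = rng.poisson(profile.walking_bouts_per_day)
    n_run = rng.poisson(profile.running_bouts_per_day)
    walk_durs = np.maximum(
        1, np.round(rng.gamma(profile.walking_dur_shape, profile.walking_dur_scale_min, n_walk))
    ).astype(int)
    run_durs = np.maximum(
        1, np.round(rng.gamma(profile.running_dur_shape, profile.running_dur_scale_min, n_run))
    ).astype(int)
    kinds = ["walking"] * n_walk + ["running"] * n_run
    blocks = _place_blocks(free, list(walk_durs) + list(run_durs), rng)
    for kind, block in zip(kinds, blocks):
        if kind == "walking":
            vals = rng.normal(profile.walking_steps_mean, profile.walking_steps_sd, len(block))
            steps[block] = np.clip(np.round(vals), 60, 139).astype(np.int64)
        else:
            vals = rng.normal(profile.running_steps_mean, profile.running_steps_sd, len(block))
            steps[block] = np.clip(np.round(vals), 140, None).astype(np.int64)
        free[block] = False

    remaining = int(round(step_target - steps.sum()))
    if remaining > 0:
        candidates = rng.permutation(np.flatnonzero(free))
        light = rng.integers(1, 60, size=len(candidates))
        csum = np.cumsum(light)
        take = int(np.searchsorted(csum, remaining)) + 1
        chosen = candidates[:take]
        steps[chosen] = light[: len(chosen)]
        if take <= len(candidates):  # trim the last filler minute to the target
            overshoot = csum[take - 1] - remaining
            steps[chosen[-1]] = max(int(light[take - 1] - overshoot), 1)

    steps[sleep] = 0
    steps[~worn] = 0

    hr = np.zeros(1440, dtype=np.int64)
    hr[worn] = 1 + rng.poisson(max(profile.hr_samples_mean - 1, 0), worn.sum())

    return pd.DataFrame(
        {
            "minute_start": pd.Timestamp(date) + pd.to_timedelta(np.arange(1440), unit="m"),
            "steps": steps,
            "hr_samples": hr,
        }
    )


def generate_cohort(
    n: int,
    profile: ActivityProfile,
    days: int,
    rng: np.random.Generator,
    start_date: dt.date = DEFAULT_START_DATE,
    wear_jitter_sd: float = 30.0,
    steps_jitter_frac: float = 0.08,
) -> list[ParticipantStream]:
    """``n`` participants × ``days`` full days, sites assigned round-robin.

    Per-participant profiles are jittered around the cohort means (wear mean
    shifted by N(0, wear_jitter_sd); step mean scaled by a log-normal factor
    with sd ``steps_jitter_frac``) so participants differ persistently, as in
    a real cohort.
    """
    if n < 1 or days < 1:
        raise ValueError("n and days must both be >= 1")
    streams = []
    for i in range(n):
        p = profile.model_copy(
            update={
                "mean_wear_minutes": float(
                    np.clip(profile.mean_wear_minutes + rng.normal(0, wear_jitter_sd), 0, 1440)
                ),
                "mean_daily_steps": profile.mean_daily_steps
                * float(rng.lognormal(0, steps_jitter_frac)),
            }
        )
        frames = [
            generate_day(p, rng, start_date + dt.timedelta(days=d)) for d in range(days)
        ]
        streams.append(
            ParticipantStream(
                participant_id=f"P{i + 1:03d}",
                site=SITES[i % len(SITES)],
                epochs=pd.concat(frames, ignore_index=True),
            )
        )
    return streams


def saturating_day(
    kind: Literal["sedentary", "walking", "running", "mixed"],
    date: dt.date = DEFAULT_START_DATE,
) -> pd.DataFrame:
    """Deterministic stress fixtures that qualify under every preset.

    * ``sedentary`` — worn zero-step minutes all day.
    * ``walking`` — 100 steps/min from 08:00 to 20:00, worn zero steps elsewhere.
    * ``running`` — 150 steps/min analogously.
    * ``mixed`` — repeating 50-minute cycles of 30 min zero steps, 10 min at
      100 steps/min, 10 min at 150 steps/min, worn throughout, so every rule
      kind finds qualifying bouts under both the original and relaxed rules.
    """
    minutes = np.arange(1440)
    steps = np.zeros(1440, dtype=np.int64)
    if kind == "walking":
        steps[(minutes >= 480) & (minutes < 1200)] = 100
    elif kind == "running":
        steps[(minutes >= 480) & (minutes < 1200)] = 150
    elif kind == "mixed":
        phase = minutes % 50
        steps[(phase >= 30) & (phase < 40)] = 100
        steps[phase >= 40] = 150
    elif kind != "sedentary":
        raise ValueError(f"unknown fixture kind {kind!r}")
    return pd.DataFrame(
        {
            "minute_start": pd.Timestamp(date) + pd.to_timedelta(minutes, unit="m"),
            "steps": steps,
            "hr_samples": np.ones(1440, dtype=np.int64),
        }
    )


def simulate_responses(
    prompts: pd.DataFrame,
    model: BehaviourModel,
    rng: np.random.Generator,
    lifecycle: PromptLifecycle | None = None,
) -> pd.DataFrame:
    """Attach answered/latency/completion outcomes to a prompt table.

    ``prompts`` needs ``participant_id``, ``day_index`` (1-based) and
    ``prompt_time`` columns; others pass through.  The response probability
    on day d is clamp(base + slope·(d−1), 0, 1); answered prompts draw a
    log-normal latency censored just below expiry and a truncated-normal
    completion time whose mean declines with the study day.
    """
    lifecycle = lifecycle or PromptLifecycle()
    out = prompts.copy().reset_index(drop=True)
    day = out["day_index"].to_numpy()
    p = np.clip(
        model.base_response_rate + model.daily_response_slope * (day - 1), 0.0, 1.0
    )
    answered = rng.random(len(out)) < p
    expiry_s = lifecycle.expiry_min * 60.0
    latency = np.minimum(
        rng.lognormal(np.log(model.latency_median_s), model.latency_log_sd, len(out)),
        expiry_s - 1.0,
    )
    completion = np.maximum(
        rng.normal(
            model.completion_mean_s + model.completion_daily_slope_s * (day - 1),
            model.completion_sd_s,
            len(out),
        ),
        model.completion_min_s,
    )
    out["answered"] = answered
    out["latency_s"] = np.where(answered, latency, np.nan)
    out["completion_s"] = np.where(answered, completion, np.nan)
    out["start_time"] = pd.NaT
    mask = answered
    out.loc[mask, "start_time"] = out.loc[mask, "prompt_time"] + pd.to_timedelta(
        out.loc[mask, "latency_s"], unit="s"
    )
    return out


def make_participants(
    n: int,
    rng: np.random.Generator,
    sites: Sequence[str] = SITES,
) -> pd.DataFrame:
    """Cohort metadata: id, site, age (~31±9, clipped 18–64), sex (56% F)."""
    ages = np.clip(np.round(rng.normal(31, 9, n)), 18, 64).astype(int)
    sex = np.where(rng.random(n) < 0.56, "F", "M")
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "site": [sites[i % len(sites)] for i in range(n)],
            "age": ages,
            "sex": sex,
        }
    )


def simulate_meal_reports(
    participants: pd.DataFrame,
    model: BehaviourModel,
    mode: Literal["self_initiated", "prompted"],
    rng: np.random.Generator,
    days: int = 7,
    start_date: dt.date = DEFAULT_START_DATE,
) -> pd.DataFrame:
    """Poisson meal/snack/drink reports per participant-day per category.

    Category rates come from the behaviour model for the given mode; the
    total daily slope is split across categories in proportion to their
    rates, and per-day rates are floored at zero.
    """
    rates = model.meal_rates_self if mode == "self_initiated" else model.meal_rates_prompted
    total = sum(rates.values())
    rows = []
    for _, part in participants.iterrows():
        for d in range(1, days + 1):
            for cat in MEAL_CATEGORIES:
                base = rates.get(cat, 0.0)
                slope_cat = model.meal_daily_slope * (base / total) if total > 0 else 0.0
                lam = max(base + slope_cat * (d - 1), 0.0)
                count = rng.poisson(lam) if lam > 0 else 0
                for _ in range(count):
                    minute = int(rng.integers(7 * 60, 23 * 60))
                    rows.append(
                        {
                            "participant_id": part["participant_id"],
                            "site": part["site"],
                            "day_index": d,
                            "category": cat,
                            "mode": mode,
                            "report_time": pd.Timestamp(start_date)
                            + pd.Timedelta(days=d - 1, minutes=minute),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "site", "day_index", "category", "mode", "report_time"],
    )
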