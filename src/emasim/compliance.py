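"""Compliance outcomes, daily trends, and self-initiated vs prompted meals.

Compliance outcomes per survey group are the median (IQR) across participants
of each participant's average: response rate (fraction of prompts started),
latency (seconds from prompt to response start, answered prompts only) and
completion time (seconds to finish, answered prompts only).

Daily trends (habituation / response fatigue) are fitted with a linear
mixed-effects model: outcome ~ day with a participant-level random intercept,
estimated by REML.  The response-rate trend is modelled on participant-day
response proportions in percentage points, so its slope reads directly as
pp/day; latency and completion trends use participant-day means of answered
prompts; the meal trend uses participant-day report counts.

The meal-mode comparison contrasts per-participant daily report averages
between self-initiated and prompted reporting with an ordinary linear model
adjusted for age and sex, per category and under either denominator (all
study days, or only days with at least one report of any type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .sweep import quantile_summary

TIME_BASED_TYPES = ("morning", "daily_1", "daily_2", "daily_3", "daily_4", "daily_5",
                    "evening", "daily")
EVENT_BASED_TYPES = ("sedentary", "walking", "running")

#: Default survey-type grouping mirroring the descriptive compliance table.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "all": TIME_BASED_TYPES + EVENT_BASED_TYPES,
    "time_based": TIME_BASED_TYPES,
    "event_based": EVENT_BASED_TYPES,
    "sedentary": ("sedentary",),
    "walking": ("walking",),
    "running": ("running",),
}

MEAL_GROUPS: dict[str, tuple[str, ...]] = {
    "all": ("breakfast", "lunch", "dinner", "snack", "drink"),
    "meals": ("breakfast", "lunch", "dinner"),
    "breakfast": ("breakfast",),
    "lunch": ("lunch",),
    "dinner": ("dinner",),
    "snacks": ("snack",),
    "drinks": ("drink",),
}


@dataclass(frozen=True)
class TrendFit:
    """Fixed-effect day slope from a random-intercept mixed model."""

    outcome: str
    slope: float
    slope_se: float
    p_value: float
    n_obs: int
    model_desc: str = "outcome ~ day, participant random intercept (REML)"

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.slope_se, self.slope + 1.96 * self.slope_se)


def summarise_compliance(
    records: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Median (IQR) of participants' average outcomes per survey group.

    ``records`` needs ``participant_id``, ``survey_type``, ``answered``, and
    (for answered prompts) ``latency_s`` / ``completion_s``.  Groups with no
    prompts are dropped with a warning; latency/completion are NaN for groups
    with no answered prompts carrying that outcome.
    """
    groups = dict(groups) if groups is not None else dict(DEFAULT_GROUPS)
    rows = []
    for name, types in groups.items():
        sub = records[records["survey_type"].isin(types)]
        if sub.empty:
            warnings.warn(f"compliance group {name!r} has no prompts; skipped")
            continue
        per_part = sub.groupby("participant_id").agg(
            response_rate=("answered", "mean"),
            latency_s=("latency_s", "mean"),
            completion_s=("completion_s", "mean"),
            n_prompts=("answered", "size"),
        )
        row = {"group": name, "n_participants": len(per_part),
               "prompts_per_day": np.nan}
        if "day_index" in sub.columns:
            per_day = sub.groupby("participant_id").agg(
                n=("answered", "size"), days=("day_index", "nunique")
            )
            med, q1, q3 = quantile_summary(per_day["n"] / per_day["days"])
            row.update(prompts_per_day=med, prompts_per_day_q1=q1, prompts_per_day_q3=q3)
        for outcome in ("response_rate", "latency_s", "completion_s"):
            vals = per_part[outcome].dropna()
            if vals.empty:
                row.update({outcome: np.nan, f"{outcome}_q1": np.nan, f"{outcome}_q3": np.nan})
                continue
            med, q1, q3 = quantile_summary(vals.to_numpy())
            row.update({outcome: med, f"{outcome}_q1": q1, f"{outcome}_q3": q3})
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def _participant_day_outcome(
    records: pd.DataFrame,
    outcome: Literal["response_rate", "latency", "completion", "meal_count"],
) -> pd.DataFrame:
    if outcome == "response_rate":
        g = records.groupby(["participant_id", "day_index"])["answered"].mean() * 100.0
    elif outcome == "latency":
        g = (
            records[records["answered"]]
            .groupby(["participant_id", "day_index"])["latency_s"].mean()
        )
    elif outcome == "completion":
        g = (
            records[records["answered"]]
            .groupby(["participant_id", "day_index"])["completion_s"].mean()
        )
    elif outcome == "meal_count":
        counts = records.groupby(["participant_id", "day_index"]).size()
        # zero-report days count as zero: complete the participant × day grid
        participants = records["participant_id"].unique()
        days = range(int(records["day_index"].min()), int(records["day_index"].max()) + 1)
        grid = pd.MultiIndex.from_product(
            [participants, days], names=["participant_id", "day_index"]
        )
        g = counts.reindex(grid, fill_value=0).astype(float)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return g.dropna().rename("value").reset_index()


def fit_daily_trend(
    records: pd.DataFrame,
    outcome: Literal["response_rate", "latency", "completion", "meal_count"],
) -> TrendFit:
    """Day slope of an outcome with a participant random intercept.

    Units: percentage points/day for ``response_rate``, seconds/day for
    ``latency`` and ``completion``, reports/day for ``meal_count``.
    """
    data = _participant_day_outcome(records, outcome)
    if data["day_index"].nunique() < 2:
        raise ValueError("trend fit needs at least 2 distinct days")
    if data["participant_id"].nunique() < 2:
        raise ValueError("trend fit needs at least 2 participants")
    endog = data["value"].to_numpy(float)
    exog = sm.add_constant(data["day_index"].to_numpy(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are fine here
        model = sm.MixedLM(endog, exog, groups=data["participant_id"].to_numpy())
        fit = model.fit(reml=True)
    return TrendFit(
        outcome=outcome,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_obs=len(data),
    )


def _daily_averages(
    reports: pd.DataFrame,
    categories: Sequence[str],
    denominator: Literal["all_days", "reporting_days"],
    n_days: int,
) -> pd.Series:
    total = reports[reports["category"].isin(categories)].groupby("participant_id").size()
    all_ids = reports["participant_id"].unique()
    total = total.reindex(all_ids, fill_value=0)
    if denominator == "all_days":
        denom = pd.Series(float(n_days), index=all_ids)
    else:
        denom = reports.groupby("participant_id")["day_index"].nunique().reindex(all_ids)
    return (total / denom).rename("daily_avg")


def compare_meal_modes(
    reports: pd.DataFrame,
    participants: pd.DataFrame,
    denominator: Literal["all_days", "reporting_days"] = "all_days",
    n_days: int = 7,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Self-initiated vs prompted daily report averages, per category.

    For each category group: per-participant daily averages under the chosen
    denominator, the median (IQR) per mode, and the mode effect
    (self-initiated minus prompted) from a linear model adjusted for age and
    sex, with its p-value.  Participants missing age or sex are excluded with
    a warning.  Only participants with at least one report appear (daily
    averages are undefined otherwise under the reporting-days denominator).
    """
    if set(reports["mode"].unique()) != {"self_initiated", "prompted"}:
        raise ValueError("reports must contain both modes")
    groups = dict(groups) if groups is not None else dict(MEAL_GROUPS)
    meta = participants.set_index("participant_id")[["age", "sex"]]
    missing = meta.index[meta[["age", "sex"]].isna().any(axis=1)]
    if len(missing):
        warnings.warn(f"excluding participants missing age/sex: {list(missing)}")
        meta = meta.drop(index=missing)
        reports = reports[~reports["participant_id"].isin(missing)]
    mode_of = reports.groupby("participant_id")["mode"].first()

    rows = []
    for name, cats in groups.items():
        avg = _daily_averages(reports, cats, denominator, n_days)
        df = (
            avg.to_frame()
            .join(mode_of)
            .join(meta, how="inner")
            .reset_index(names="participant_id")
        )
        df["is_self"] = (df["mode"] == "self_initiated").astype(float)
        fit = smf.ols("daily_avg ~ is_self + age + C(sex)", data=df).fit()
        med_s, q1_s, q3_s = quantile_summary(df.loc[df["is_self"] == 1, "daily_avg"])
        med_p, q1_p, q3_p = quantile_summary(df.loc[df["is_self"] == 0, "daily_avg"])
        rows.append(
            {
                "group": name,
                "self_median": med_s, "self_q1": q1_s, "self_q3": q3_s,
                "prompted_median": med_p, "prompted_q1": q1_p, "prompted_q3": q3_p,
                "mode_effect": float(fit.params["is_self"]),
                "mode_se": float(fit.bse["is_self"]),
                "p_value": float(fit.pvalues["is_self"]),
                "n_self": int((df["is_self"] == 1).sum()),
                "n_prompted": int((df["is_self"] == 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
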