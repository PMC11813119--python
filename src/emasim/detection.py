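"""Detection of qualifying sedentary / walking / running bouts.

A bout rule asks for ``duration_min`` *consecutive recorded* minutes whose
step counts sit inside [step_low, step_high], tolerating up to
``outlier_allowance`` violating minutes in a single permitted direction
(above the upper bound or below the lower bound).  The protocol rules are:

* sedentary — zero steps (low = high = 0), heart rate present every minute
  so that non-wear is not mistaken for sitting;
* walking — 60–139 steps/min;
* running — ≥140 steps/min.

Semantics fixed here (the configuration language leaves them open):

* Bouts are emitted per qualifying *end minute* at exactly the rule duration,
  not as maximal runs: the trigger engine only ever asks "does a qualifying
  window end at minute m", and this makes that query O(1).
* The first and last minutes of a window must themselves satisfy the step
  bounds (outliers cannot anchor a window) — otherwise a walking bout could
  end on two stationary minutes, defeating the aim of prompting close to the
  behaviour.
* Outlier minutes count toward the duration: a 5-minute walking window may
  contain 2 tolerated outliers and 3 in-range minutes.
* A minute absent from the stream never participates in a window (windows
  need consecutive recorded minutes).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

Kind = Literal["sedentary", "walking", "running"]
OutlierDirection = Literal["above_high", "below_low", "none"]

BOUT_COLUMNS = ["start_minute", "end_minute", "kind", "n_outliers"]


class EventRule(BaseModel):
    """Parameterisation of one event-detection rule."""

    kind: Kind
    duration_min: int
    step_low: Optional[int] = None
    step_high: Optional[int] = None
    outlier_allowance: int = 0
    outlier_direction: OutlierDirection = "none"
    require_hr_each_minute: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EventRule":
        if self.duration_min < 1:
            raise ValueError("duration_min must be >= 1")
        if not 0 <= self.outlier_allowance < self.duration_min:
            raise ValueError("outlier_allowance must be in [0, duration_min)")
        if (self.outlier_direction == "none") != (self.outlier_allowance == 0):
            raise ValueError("outlier_direction is 'none' iff allowance is 0")
        if self.outlier_direction == "above_high" and self.step_high is None:
            raise ValueError("above_high outliers need a step_high bound")
        if self.outlier_direction == "below_low" and self.step_low is None:
            raise ValueError("below_low outliers need a step_low bound")
        if self.step_low is None and self.step_high is None:
            raise ValueError("rule needs at least one step bound")
        return self


def _classify(epochs: pd.DataFrame, rule: EventRule):
    """Per-minute flags: in-range, tolerated outlier, disqualifying minute."""
    steps = epochs["steps"].to_numpy()
    hr = epochs["hr_samples"].to_numpy()
    below = steps < rule.step_low if rule.step_low is not None else np.zeros(len(steps), bool)
    above = steps > rule.step_high if rule.step_high is not None else np.zeros(len(steps), bool)
    viol = below | above
    if rule.outlier_direction == "above_high":
        allowed = above
    elif rule.outlier_direction == "below_low":
        allowed = below
    else:
        allowed = np.zeros(len(steps), bool)
    bad = viol & ~allowed
    if rule.require_hr_each_minute:
        bad = bad | (hr < 1)
    return ~viol, viol & allowed, bad


def find_bouts(epochs: pd.DataFrame, rule: EventRule) -> pd.DataFrame:
    """All qualifying windows of ``rule.duration_min`` recorded minutes.

    Returns a DataFrame with one row per qualifying end minute, columns
    ``start_minute``, ``end_minute`` (civil time of the last included
    minute), ``kind`` and ``n_outliers``, ordered by end minute.
    """
    ts = epochs["minute_start"]
    t = ts.to_numpy().astype("datetime64[m]").astype(np.int64)
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValueError("stream must be sorted with no duplicate minutes")
    d = rule.duration_min
    n = len(t)
    if n < d:
        return pd.DataFrame(columns=BOUT_COLUMNS)

    ok, tolerated, bad = _classify(epochs, rule)
    cb = np.concatenate([[0], np.cumsum(bad)])
    ct = np.concatenate([[0], np.cumsum(tolerated)])
    ends = np.arange(d - 1, n)
    starts = ends - d + 1
    contiguous = (t[ends] - t[starts]) == d - 1
    bad_in_win = cb[ends + 1] - cb[starts]
    out_in_win = ct[ends + 1] - ct[starts]
    qual = (
        contiguous
        & (bad_in_win == 0)
        & (out_in_win <= rule.outlier_allowance)
        & ok[starts]
        & ok[ends]
    )
    idx = ends[qual]
    return pd.DataFrame(
        {
            "start_minute": ts.to_numpy()[idx - d + 1],
            "end_minute": ts.to_numpy()[idx],
            "kind": rule.kind,
            "n_outliers": out_in_win[qual].astype(int),
        }
    )


def brute_force_bouts(epochs: pd.DataFrame, rule: EventRule) -> pd.DataFrame:
    """Reference implementation: exhaustively test every window.

    Same contract as :func:`find_bouts`, written from the rule definition
    with plain loops.  Intended as a test oracle; do not use on long streams.
    """
    ts = list(epochs["minute_start"].to_numpy().astype("datetime64[m]").astype(int))
    steps = list(epochs["steps"])
    hr = list(epochs["hr_samples"])
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("stream must be sorted with no duplicate minutes")
    d = rule.duration_min
    out = []
    for start in range(len(ts) - d + 1):
        if ts[start + d - 1] - ts[start] != d - 1:
            continue  # a gap: minutes not consecutive
        n_outliers = 0
        qualifies = True
        for pos in range(start, start + d):
            s = steps[pos]
            too_low = rule.step_low is not None and s < rule.step_low
            too_high = rule.step_high is not None and s > rule.step_high
            if rule.require_hr_each_minute and hr[pos] < 1:
                qualifies = False
                break
            if too_low or too_high:
                if pos in (start, start + d - 1):  # anchors must be in range
                    qualifies = False
                    break
                direction_ok = (too_high and rule.outlier_direction == "above_high") or (
                    too_low and rule.outlier_direction == "below_low"
                )
                if not direction_ok:
                    qualifies = False
                    break
                n_outliers += 1
                if n_outliers > rule.outlier_allowance:
                    qualifies = False
                    break
        if qualifies:
            out.append(
                {
                    "start_minute": epochs["minute_start"].iloc[start],
                    "end_minute": epochs["minute_start"].iloc[start + d - 1],
                    "kind": rule.kind,
                    "n_outliers": n_outliers,
                }
            )
    return pd.DataFrame(out, columns=BOUT_COLUMNS)
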