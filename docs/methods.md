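# Methods

## Problem and scope

`emasim` re-creates, as reusable software, the computational machinery of a
sensor-triggered ecological momentary assessment (EMA) protocol for physical
and eating behaviours: a wrist tracker streams step counts in minute epochs
(plus heart-rate samples used as a wear proxy), a server evaluates the stream
at each sync against behavioural rules and pushes surveys, and the analysis
stage quantifies compliance and reporting behaviour.  The package covers
five stages — stream model and wear filtering, bout detection, trigger
simulation, protocol parameter sweeps, and compliance/meal analysis — plus a
synthetic cohort generator so every stage is testable without device data.

## Stream model

An epoch is a half-open minute `[t, t+60 s)` holding a step count and the
number of heart-rate samples logged in that minute.  Times are local civil
times; streams are assumed DST-free and day boundaries fall at 00:00.  A
minute is *worn* iff it has ≥1 heart-rate sample; a *valid day* has ≥600
worn minutes (10 h).  Minutes absent from a stream count as not-worn for
wear accounting but are distinguishable from recorded zeros: event rules
need "zero steps while worn", and an unrecorded minute can never satisfy
that.  The same ≥1-sample criterion is used both for valid-day wear and for
the sedentary rule's wear control; the protocol description does not
distinguish them and we take them to be identical.

## Bout detection

A rule asks for `duration_min` consecutive recorded minutes inside step
bounds, tolerating up to `outlier_allowance` violations in one direction
only.  Three semantic choices were genuinely open and are fixed as follows:

* **Per-end-minute emission.**  Bouts are emitted at exactly the rule
  duration, one per qualifying end minute, rather than as maximal runs.  The
  trigger engine only ever asks "does a qualifying window end at minute m?",
  so this makes the sync-time query a lookup, and it makes the exhaustive
  test oracle trivial to state.
* **Anchor constraint.**  The first and last minutes of a window must
  themselves satisfy the bounds.  Without this, a walking bout could end on
  two tolerated stationary minutes, contradicting the aim of prompting as
  close to the behaviour as possible.  A consequence worth noting: the
  intuitive claim "shortening the duration never removes a qualifying
  end-minute" holds only for outlier-free rules, because a shortened window
  may start on a minute that was a tolerated outlier in the longer window.
  The property suite tests duration-monotonicity in the outlier-free form
  and allowance-monotonicity in general.
* **Outliers count toward the duration**, so a 5-minute walking window may
  hold 2 outliers and 3 in-range minutes.

Sedentary rules additionally require heart rate in every window minute (so
non-wear is not read as sitting); walking/running rules do not (steps imply
wear).  The original-protocol running rule's outlier tolerance is ambiguous
in the protocol text; the shipped `cz_de_original` preset sets it to 0, and
`ie_fr_relaxed` mirrors the walking relaxation (2 below-threshold outliers,
5-minute duration).  This is an interpretation, flagged here.

## Trigger simulation

The tracker uploads only at syncs (regular 15-minute cadence by default; a
jittered mode exists for sensitivity analyses).  At each sync, for each rule
kind, the *most recent* unconsumed bout whose end minute lies within the
backwards span `[t − span, t)` is the candidate — most recent, so the survey
refers to the freshest event.  The candidate fires iff the per-kind 90-min
refractory interval, the clock-window caps (sedentary: 2 in 08:00–14:00 and
2 in 14:00–20:00), the per-kind daily caps (3 walking, 3 running) and the
joint daily cap (10) all allow it.  Further fixed choices, all matching how
a real-time server would behave where the protocol text is silent:

* scheduling is greedy-chronological; ties at one sync resolve
  sedentary → walking → running, with the joint cap checked per firing;
* the refractory interval spans midnight; caps reset at midnight;
* sedentary clock windows constrain the *fire time*, not the bout location;
* a fired bout is consumed and never re-fires; at most one trigger per kind
  per sync;
* the joint 10/day cap is applied across kinds (configurable, since the live
  system's behaviour is not documented).

With a 17-minute span and regular 15-minute syncs every detected bout falls
inside some sync's lookback window (17 > 15 + 1), so any untriggered bout is
attributable to constraint filtering alone; this completeness property is
tested on random cohorts.  With span 1 the bout must persist to the final
minute before the sync, and trigger delay is 0.

Time-based surveys are pre-drawn for the whole study, one uniform minute per
frame per day over the seven frames (06:00–09:45, 10:15–11:45, 12:15–13:45,
14:15–15:45, 16:15–17:45, 18:15–19:45, 20:15–22:00, inclusive bounds at
minute resolution); the frame layout itself guarantees a 30-minute floor on
inter-prompt gaps.  The prompt lifecycle issues reminders at 3, 6 and 7
minutes and expires surveys at 8 minutes (configurable; 15 is a commonly
recommended relaxation); a response starting at or after expiry counts as
unanswered.

## Protocol sweeps

`run_sweep` evaluates labelled rule variants on a cohort already filtered to
participants with a full week of valid days: detect bouts, simulate triggers
per participant, average triggers/day over that participant's valid days,
then summarise across participants as median (IQR).  Quantiles use linear
interpolation (type 7), fixed and documented because the convention the
original analysis used is unknowable.  The shipped grids vary one parameter
at a time from the original rules (backwards span 17, one outlier, shorter
duration) plus the combined "Optimal" rows.  Absolute medians depend
entirely on the cohort's activity patterns, so on synthetic cohorts only the
grid structure, the cap bounds (≤4 sedentary, ≤3 walking per day) and the
relaxation orderings are meaningful.  For the sedentary grid, "Original ≤
each single relaxation" is provable per participant (a relaxed rule detects
a superset of bouts, and a larger span yields candidates at a superset of
syncs); "single relaxation ≤ Optimal" mixes a schedule relaxation with a
detection relaxation and is checked empirically on the seeded default
cohort, where it holds.

## Compliance and meal analysis

Per-group compliance outcomes are medians (IQRs) across participants of
participant averages: response rate (fraction of prompts started), latency
(prompt → response start, answered prompts only — whether the original
analysis restricted latency to answered prompts is unstated; we do) and
completion time.  Daily trends are linear mixed-effects fits with a fixed
day effect and a participant random intercept, estimated by REML
(`statsmodels` MixedLM; the estimation method was not documented and REML is
the conventional default).  The response-rate trend is fitted on
participant-day response *proportions* in percentage points — the simplest
model whose slope reads directly in pp/day — rather than on per-prompt
binary outcomes; this is a declared choice, not the only defensible one.

The meal-mode comparison computes per-participant daily report averages
under one of two denominators (all 7 study days, or only days with ≥1 report
of *any* type) and contrasts self-initiated vs prompted modes per category
with an ordinary linear model adjusted for age and sex.  Only participants
with at least one report enter (the reporting-days denominator is undefined
otherwise).

## Synthetic cohort generator

The generator reproduces the statistics the analyses assume, not physiology:

* **Wear.**  Daily non-wear is drawn from a gamma distribution with mean
  `1440 − 1357 = 83` min and sd 124 min — right-skewed, so most days are
  near-full wear with occasional long (recharge-like) gaps, and the
  1440-minute ceiling introduces no truncation bias.  Gaps (1–3 per day)
  land only in waking time.  Sleep (default 23:00–07:00) is worn with zero
  steps.
* **Steps.**  A daily target is drawn from N(11 189, 2 881).  Walking bouts
  (Poisson, 3/day; Gamma(2, 5 min) durations; ~N(100, 15) steps/min clipped
  to 60–139) and running bouts (Poisson, 0.4/day; ~N(160, 10) clipped at
  ≥140) are placed as contiguous blocks; remaining waking worn minutes
  receive light-activity steps (uniform 1–59) until the target is met, with
  the last filler minute trimmed so the daily total matches the target
  exactly.  Bout-heavy days occasionally overshoot the target on bouts
  alone; with the default mix this inflates the mean by well under 1 %.
* **Cohort heterogeneity.**  Per-participant wear and step means are
  jittered (sd 30 min; log-normal factor sd 0.08) so participants differ
  persistently.
* **Behaviour.**  Response probability is linear in the study day with
  clamping to [0, 1] — the trend analysis reports percentage points per day
  and the underlying link is unstated, so the generator uses the linear
  probability form (base 0.55 on day 1, slope −0.0166/day, giving a 7-day
  mean ≈ 0.49).  Latency is log-normal (median 127 s, log-sd 0.6) censored
  just below the 8-minute expiry; completion is normal (72 ± 15 s, slope
  −1.62 s/day) floored at 10 s.  Meal/snack/drink counts are Poisson per
  participant-day per category, with category rates summing to 4.0/day
  (self-initiated) and 1.4/day (prompted) and a total slope of −0.17/day
  apportioned proportionally, floored at zero.

What the generator does *not* emulate: circadian activity structure beyond
the sleep window, autocorrelated activity across days, irregular real-world
sync cadences, weekday/weekend effects, or any dependence of response
behaviour on context.  Passing recovery tests therefore show that the
analysis layer is a consistent estimator of the generative trends at study
scale — not that real cohorts satisfy the generative assumptions.

## Problem sizes and numerical choices

The test suite exercises the oracle equivalence on 1 000 random 70-minute
streams per rule, the sweep orderings on a 46-participant × 7-day cohort,
and the trend recoveries on 100 seeded replicates at study scale
(46 × 7 × 10 prompts/day), with the meal-mode power check on 40 replicates
of 25 participants per arm — sizes chosen to make the statistical checks
decisive while keeping the default run quick.  Recovery tests assert the
replicate mean within three standard errors of the generating slope and
≥85 % nominal-95 % CI coverage.  Degenerate inputs are rejected loudly:
trend fits need ≥2 days and ≥2 participants, quantile summaries need
non-empty input, sweeps need a non-empty filtered cohort.  Mixed-model fits
on noiseless data sit on the boundary of the variance parameter space;
boundary warnings are suppressed inside `fit_daily_trend` and the slope is
still recovered to machine precision (asserted at 1e-8).

## Known limitations

* The detector's anchor rule and outlier accounting are one reasonable
  resolution of an under-specified configuration language; other platforms
  may differ at windows' edges.
* Trigger scheduling is deterministic given bouts and syncs; the live
  system's behaviour under racing rules or missed syncs is not modelled
  beyond the jittered sync mode.
* Absolute sweep medians on synthetic cohorts are far below field values —
  scattered light-activity filler breaks long zero-step runs more often
  than real behaviour does — so only orderings and cap-bounded results
  transfer.
* The meal-mode comparison inherits the design's confound: mode is assigned
  by site, so "adjusted for age and sex" is not causal identification.
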