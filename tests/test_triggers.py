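import datetime as dt

import numpy as np
import pandas as pd
import pytest

from emasim import (
    EventRule,
    PromptLifecycle,
    ScheduleConstraints,
    SyncModel,
    TIME_BASED_WINDOWS,
    WindowCap,
    apply_lifecycle,
    find_bouts,
    saturating_day,
    schedule_time_based,
    simulate_event_triggers,
    sync_times,
)

from conftest import DATE, make_epochs


class TestSyncTimes:
    def test_regular_fifteen_minutes_gives_96(self):
        assert len(sync_times(SyncModel(), DATE)) == 96

    def test_whole_day_period_gives_one(self):
        assert len(sync_times(SyncModel(period_min=1440), DATE)) == 1

    def test_jittered_reproducible_and_sorted(self):
        sm = SyncModel(mode="jittered", jitter_sd_min=2.0)
        a = sync_times(sm, DATE, np.random.default_rng(5))
        b = sync_times(sm, DATE, np.random.default_rng(5))
        assert (a == b).all()
        assert a.is_monotonic_increasing
        with pytest.raises(ValueError, match="rng"):
            sync_times(sm, DATE)

    def test_offset_validation(self):
        with pytest.raises(ValueError):
            SyncModel(period_min=15, offset_min=15)


class TestEventTriggers:
    def test_saturating_sedentary_day_fires_four(self, ie_fr):
        bouts = find_bouts(saturating_day("sedentary"), ie_fr.rules["sedentary"].rule)
        trig = simulate_event_triggers(
            {"sedentary": bouts}, ie_fr.sync, ie_fr.constraints_by_kind, [DATE],
            ie_fr.total_daily_cap,
        )
        assert len(trig) == 4
        gaps = trig["fire_time"].diff().dropna()
        assert (gaps >= pd.Timedelta(minutes=90)).all()
        hours = trig["fire_time"].dt.hour
        assert ((8 <= hours) & (hours < 14)).sum() == 2
        assert ((14 <= hours) & (hours < 20)).sum() == 2

    def test_saturating_walking_day_fires_three(self, ie_fr):
        bouts = find_bouts(saturating_day("walking"), ie_fr.rules["walking"].rule)
        trig = simulate_event_triggers(
            {"walking": bouts}, ie_fr.sync, ie_fr.constraints_by_kind, [DATE],
            ie_fr.total_daily_cap,
        )
        assert len(trig) == 3

    def test_backwards_span_controls_reach(self):
        # one 20-minute zero-step bout ending five minutes before the only sync
        epochs = make_epochs([0] * 20, start="2023-03-06 01:40")  # ends 01:59
        rule_bouts = find_bouts(
            epochs,
            EventRule(kind="sedentary", duration_min=20, step_low=0, step_high=0,
                      require_hr_each_minute=True),
        )
        bout = rule_bouts.iloc[[-1]]  # end minute 01:59, bout over at 02:00
        sync = SyncModel(period_min=1440, offset_min=125)  # single sync at 02:05
        for span, expected in [(1, 0), (17, 1)]:
            c = ScheduleConstraints(backwards_span_min=span, min_interval_min=90)
            trig = simulate_event_triggers(
                {"sedentary": bout}, sync, {"sedentary": c}, [DATE], None
            )
            assert len(trig) == expected, f"span {span}"
        c17 = ScheduleConstraints(backwards_span_min=17, min_interval_min=90)
        trig = simulate_event_triggers({"sedentary": bout}, sync, {"sedentary": c17}, [DATE], None)
        assert trig["delay_min"].iloc[0] == 5.0

    def test_most_recent_bout_wins_and_fires_once(self):
        ends = pd.to_datetime(["2023-03-06 01:57", "2023-03-06 01:59"])
        bouts = pd.DataFrame(
            {"start_minute": ends - pd.Timedelta(minutes=19), "end_minute": ends,
             "kind": "sedentary", "n_outliers": 0}
        )
        c = ScheduleConstraints(backwards_span_min=17, min_interval_min=0)
        trig = simulate_event_triggers(
            {"sedentary": bouts}, SyncModel(), {"sedentary": c}, [DATE], None
        )
        fired = trig[trig["fire_time"] == pd.Timestamp("2023-03-06 02:00")]
        assert fired["bout_end"].iloc[0] == pd.Timestamp("2023-03-06 01:59")
        # the same bout never fires twice
        assert not trig["bout_end"].duplicated().any()

    def test_min_interval_spans_midnight(self):
        ends = pd.to_datetime(["2023-03-06 23:44", "2023-03-07 00:14"])
        bouts = pd.DataFrame(
            {"start_minute": ends - pd.Timedelta(minutes=19), "end_minute": ends,
             "kind": "walking", "n_outliers": 0}
        )
        c = ScheduleConstraints(backwards_span_min=1, min_interval_min=90)
        trig = simulate_event_triggers(
            {"walking": bouts}, SyncModel(), {"walking": c},
            [DATE, DATE + dt.timedelta(days=1)], None,
        )
        assert len(trig) == 1  # second bout suppressed by the 90-min refractory

    def test_total_daily_cap_enforced_across_kinds(self, ie_fr):
        day = saturating_day("mixed")
        bouts = {k: find_bouts(day, rc.rule) for k, rc in ie_fr.rules.items()}
        trig = simulate_event_triggers(
            bouts, ie_fr.sync, ie_fr.constraints_by_kind, [DATE], total_daily_cap=5
        )
        assert len(trig) == 5

    def test_relaxing_constraints_never_reduces_triggers(self, ie_fr):
        bouts = find_bouts(saturating_day("sedentary"), ie_fr.rules["sedentary"].rule)
        base = ie_fr.constraints_by_kind["sedentary"]
        n_base = len(simulate_event_triggers(
            {"sedentary": bouts}, ie_fr.sync, {"sedentary": base}, [DATE], None))
        relaxations = [
            base.model_copy(update={"min_interval_min": 30}),
            base.model_copy(update={"windows": [
                WindowCap(start="08:00", end="14:00", cap=5),
                WindowCap(start="14:00", end="20:00", cap=5)]}),
            base.model_copy(update={"windows": [
                WindowCap(start="06:00", end="14:00", cap=2),
                WindowCap(start="14:00", end="22:00", cap=2)]}),
        ]
        for c in relaxations:
            n = len(simulate_event_triggers(
                {"sedentary": bouts}, ie_fr.sync, {"sedentary": c}, [DATE], None))
            assert n >= n_base

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ScheduleConstraints(
                backwards_span_min=1,
                windows=[WindowCap(start="08:00", end="14:00", cap=2),
                         WindowCap(start="13:00", end="20:00", cap=2)],
            )


class TestTimeBasedSchedule:
    def test_seven_prompts_per_day_inside_windows(self):
        days = [DATE + dt.timedelta(days=d) for d in range(7)]
        sched = schedule_time_based(days, np.random.default_rng(0))
        assert len(sched) == 49
        bounds = {label: (start, end) for label, start, end in TIME_BASED_WINDOWS}
        for _, row in sched.iterrows():
            start, end = bounds[row["survey_type"]]
            hhmm = row["prompt_time"].strftime("%H:%M")
            assert start <= hhmm <= end
        assert (sched.groupby("date").size() == 7).all()

    def test_minimum_gap_thirty_minutes(self):
        days = [DATE + dt.timedelta(days=d) for d in range(30)]
        sched = schedule_time_based(days, np.random.default_rng(1))
        gaps = sched.sort_values("prompt_time")["prompt_time"].diff().dropna()
        assert gaps.min() >= pd.Timedelta(minutes=30)

    def test_fixed_seed_reproducible(self):
        a = schedule_time_based([DATE], np.random.default_rng(7))
        b = schedule_time_based([DATE], np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)


class TestPromptLifecycle:
    def test_unanswered_prompt_expires_with_all_reminders(self):
        t = pd.Timestamp("2023-03-06 10:00")
        rec = apply_lifecycle(t, PromptLifecycle(), latency_s=None)
        assert not rec["answered"]
        assert rec["expiry_time"] == t + pd.Timedelta(minutes=8)
        assert rec["reminder_times"] == [t + pd.Timedelta(minutes=m) for m in (3, 6, 7)]

    def test_immediate_answer_no_reminders(self):
        rec = apply_lifecycle(pd.Timestamp("2023-03-06 10:00"), PromptLifecycle(), 0.0)
        assert rec["answered"] and rec["reminder_times"] == []

    def test_answer_at_seven_and_a_half_minutes_after_three_reminders(self):
        t = pd.Timestamp("2023-03-06 10:00")
        rec = apply_lifecycle(t, PromptLifecycle(), latency_s=450.0)
        assert rec["answered"]
        assert len(rec["reminder_times"]) == 3
        assert rec["start_time"] == t + pd.Timedelta(seconds=450)

    def test_start_after_expiry_rejected(self):
        rec = apply_lifecycle(pd.Timestamp("2023-03-06 10:00"), PromptLifecycle(), 480.0)
        assert not rec["answered"] and rec["start_time"] is None

    def test_reminders_must_precede_expiry(self):
        with pytest.raises(ValueError):
            PromptLifecycle(reminder_offsets_min=(3, 6, 9), expiry_min=8)


class TestTriggerInvariantsOnRandomCohorts:
    def test_caps_gaps_and_delays_hold_on_generated_activity(self, ie_fr):
        from emasim import ActivityProfile, generate_cohort

        rng = np.random.default_rng(11)
        cohort = generate_cohort(3, ActivityProfile(), 3, rng)
        for stream in cohort:
            bouts = {k: find_bouts(stream.epochs, rc.rule) for k, rc in ie_fr.rules.items()}
            trig = simulate_event_triggers(
                bouts, ie_fr.sync, ie_fr.constraints_by_kind, stream.study_days,
                ie_fr.total_daily_cap,
            )
            if trig.empty:
                continue
            trig = trig.assign(date=trig["fire_time"].dt.date)
            assert (trig.groupby("date").size() <= 10).all()
            for kind, sub in trig.groupby("kind"):
                c = ie_fr.constraints_by_kind[kind]
                gaps = sub["fire_time"].sort_values().diff().dropna()
                assert (gaps >= pd.Timedelta(minutes=c.min_interval_min)).all()
                assert (sub["delay_min"] >= 0).all()
                assert (sub["delay_min"] <= c.backwards_span_min).all()
                if c.daily_cap is not None:
                    assert (sub.groupby("date").size() <= c.daily_cap).all()
                for i, w in enumerate(c.windows):
                    minute = sub["fire_time"].dt.hour * 60 + sub["fire_time"].dt.minute
                    in_w = (w.start_min <= minute) & (minute < w.end_min)
                    assert (sub[in_w].groupby("date").size() <= w.cap).all()
                if c.windows:
                    minute = sub["fire_time"].dt.hour * 60 + sub["fire_time"].dt.minute
                    in_any = np.zeros(len(sub), dtype=bool)
                    for w in c.windows:
                        in_any |= ((w.start_min <= minute) & (minute < w.end_min)).to_numpy()
                    assert in_any.all()
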