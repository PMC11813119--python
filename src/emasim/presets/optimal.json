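{
  "name": "optimal",
  "description": "Settings the trigger-optimisation simulations found to hit the target survey counts (4 sedentary, 3 walking per day). No running rule: running events were too rare to simulate.",
  "sync": {"period_min": 15, "offset_min": 0, "mode": "regular"},
  "lifecycle": {"reminder_offsets_min": [3, 6, 7], "expiry_min": 8},
  "total_daily_cap": 10,
  "rules": {
    "sedentary": {
      "rule": {
        "kind": "sedentary", "duration_min": 20,
        "step_low": 0, "step_high": 0,
        "outlier_allowance": 0, "outlier_direction": "none",
        "require_hr_each_minute": true
      },
      "constraints": {
        "backwards_span_min": 1, "min_interval_min": 90,
        "windows": [
          {"start": "08:00", "end": "14:00", "cap": 2},
          {"start": "14:00", "end": "20:00", "cap": 2}
        ],
        "daily_cap": 4
      }
    },
    "walking": {
      "rule": {
        "kind": "walking", "duration_min": 5,
        "step_low": 60, "step_high": 139,
        "outlier_allowance": 2, "outlier_direction": "below_low",
        "require_hr_each_minute": false
      },
      "constraints": {
        "backwards_span_min": 17, "min_interval_min": 90,
        "windows": [], "daily_cap": 3
      }
    }
  }
}
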