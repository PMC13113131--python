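# Bundled example shelter: four kennel tiers of decreasing visibility and
# two animal tracks, each with one intake per day on average.
scenario:
  priority: S
  tiers:
    - {name: spotlight, capacity: 1, multiplier: 3.0, rank: 1}
    - {name: showcase, capacity: 7, multiplier: 1.5, rank: 2}
    - {name: standard, capacity: 18, multiplier: 1.0, rank: 3}
    - {name: overflow, capacity: unbounded, multiplier: 0.5, rank: 4}
  tracks:
    - {name: slow, baseline_los_days: 27.0, intake_per_day: 1.0}
    - {name: fast, baseline_los_days: 3.0, intake_per_day: 1.0}
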