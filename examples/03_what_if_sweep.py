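"""What-if sweep: how alarm settings change the burden.

Re-derives the alarm stream from raw SpO2/PR under alternative monitor
settings — longer delays, a lower SpO2 limit of 80%, a disabled upper
limit — and prints one row per settings point. This is the alarm-hygiene
question: how many alarms would the unit have heard under different
thresholds, and how much data would sit outside them?
"""

from dataclasses import replace

import oxiburden as ox

spec = replace(ox.default_calibration(), n_neonates=4, seed=31,
               duration_median_d=1.0, duration_min_d=0.5, duration_max_d=2.0)
traces, _ = ox.generate_cohort(spec)
filtered = [ox.apply_quality_rules(tr)[0] for tr in traces]

grid = ox.expand_grid(ox.DEFAULT_SETTINGS, delay_s=[15.0, 30.0])
grid += ox.expand_grid(replace(ox.DEFAULT_SETTINGS, spo2_low=80.0), delay_s=[15.0])
grid += [replace(ox.DEFAULT_SETTINGS, spo2_high=None)]

results = ox.what_if_sweep(filtered, grid)
table = ox.sweep_to_frame(results)
cols = ["spo2_low", "spo2_high", "delay_s", "total_alarms", "alarms_per_hour",
        "spo2_below_frac", "spo2_above_frac"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
base, *_ = results
print(
    f"\nbaseline: {base.total_alarms} alarms "
    f"({base.alarms_per_hour:.1f}/h). Each subsequent row shows the burden"
)
print("under one alarm-hygiene change (longer delay, lower limit 80%, no upper limit).")
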