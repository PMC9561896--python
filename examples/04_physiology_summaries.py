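"""Plausibility filtering and descriptive physiology tables.

Temperature records outside 34-41 C (a detached patch logs ambient air)
are flagged, never silently deleted; the remaining records feed daily
step/energy/sleep summaries, a six-number quantile table and an
hour-of-day activity profile that shows the configured midday dip.
"""

import dataclasses

from wearcov import StudyDesign, validate_records
from wearcov.physiology_summaries import (
    daily_summary,
    default_rules,
    diurnal_profile,
    filter_plausible,
    quantile_table,
)
from wearcov.synthetic_cohort import SyntheticConfig, TemperatureConfig, simulate_study

design = StudyDesign(n_cycles=1, participants_per_cycle=10,
                     arm1_per_cycle=5, arm2_per_cycle=5)
config = dataclasses.replace(
    SyntheticConfig(seed=5), design=design,
    temperature=TemperatureConfig(detach_prob_per_night=0.5,
                                  record_when_detached=True))
data = simulate_study(config)
records, _ = validate_records(data["measurements"], data["roster"])

kept, flagged, counts = filter_plausible(records, default_rules())
print("plausibility filter:", counts["temperature"])

summary = daily_summary(kept, data["roster"])
observed = summary[summary["has_data"]]
table = quantile_table({
    "steps_per_day": observed["steps"],
    "kcal_per_day": observed["kcal"],
    "sleep_h_per_day": observed["sleep_h"].dropna(),
    "heart_rate_bpm": kept.loc[kept["stream"] == "heart_rate", "value"],
})
print(table.round(1).to_string(index=False))

profile = diurnal_profile(kept, "steps_sum")
dip = profile[(profile.hour >= 12) & (profile.hour < 18)]["mean"].mean()
morning = profile[(profile.hour >= 8) & (profile.hour < 12)]["mean"].mean()
print(f"midday/morning activity ratio: {dip / morning:.2f} "
      f"(configured dip factor {config.activity.midday_dip_factor})")
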