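"""Generate a synthetic wearable study and inspect its structure.

A small one-cycle cohort (10 participants, 5 per arm) with the default
wear, activity, sleep and attrition behaviour.  Per-stream record counts
show the device cadences at work: near-continuous step epochs during
daytime wear, sparse photoplethysmography heart-rate reads, and
per-minute thermometer records on the few nights the patch stays on.
"""

import dataclasses

from wearcov import StudyDesign
from wearcov.synthetic_cohort import SyntheticConfig, simulate_study

design = StudyDesign(n_cycles=1, participants_per_cycle=10,
                     arm1_per_cycle=5, arm2_per_cycle=5)
config = dataclasses.replace(SyntheticConfig(seed=7), design=design)
data = simulate_study(config)

roster = data["roster"]
print(f"cohort: {len(roster)} participants "
      f"({(roster.arm == 1).sum()} wristband-only, "
      f"{(roster.arm == 2).sum()} wristband+patch), "
      f"ages {roster.age_years.min()}-{roster.age_years.max()} "
      f"(median {roster.age_years.median():.0f})")
print("records per stream after sync loss and device failure:")
print(data["measurements"].groupby("stream").size().to_string())
failures = data["device_failures"]
failed = failures[failures["failure_day"].between(1, 21)]
print(f"devices failing during the study: {len(failed)} of {len(failures)}")
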