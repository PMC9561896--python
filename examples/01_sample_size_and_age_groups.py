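"""Study-design utilities: Cochran sample size with FPC, quantile age groups.

The deployment drew its cohort from a surveillance population of roughly
100,000 residents older than 6; with 95% confidence and an 8% margin of
error the corrected Cochran formula gives the 150 participants the study
enrolled.  Age subgroups are quartile-based so each holds ~25% of the
cohort.
"""

import numpy as np

from wearcov import assign_age_groups, sample_size_fpc

n = sample_size_fpc(population=100_000, confidence=0.95, margin=0.08,
                    proportion=0.5)
print(f"required sample size: {n} participants")

ages = np.clip(np.round(6 + 78 * np.random.default_rng(0).beta(1.2, 2.8, 150)),
               6, 84).astype(int)
labels, cuts = assign_age_groups(ages)
print(f"age quartile cut points: {cuts}")
for label in dict.fromkeys(sorted(labels, key=lambda s: int(s.split('-')[0]))):
    print(f"  group {label}: {(labels == label).sum()} participants")
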