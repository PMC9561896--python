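"""Likert positive agreement and multiple-choice tabulation.

Seventeen five-point items in three categories; negatively worded items
are reverse-coded (r -> 6 - r) before counting the top-two-box share.
Multiple-choice percentages are always printed with their denominator,
because feasibility reports are notorious for shifting bases.
"""

import dataclasses

from wearcov.acceptability_analysis import (
    category_summary,
    default_likert_catalog,
    default_mc_catalog,
    positive_agreement,
    subgroup_table,
    tabulate_mc,
)
from wearcov.synthetic_cohort import SyntheticConfig, simulate_study

data = simulate_study(dataclasses.replace(SyntheticConfig(seed=9)))
catalog = default_likert_catalog()

agreements = positive_agreement(data["likert"], catalog)
print(category_summary(agreements, catalog, threshold=0.9)
      .round(3).to_string(index=False))

mc = tabulate_mc(data["mc"], default_mc_catalog(),
                 denominator_policy="respondents")
challenges = mc[mc["question_id"] == "challenges"]
print("\nchallenges this week (of all questionnaires):")
print(challenges[["option", "count", "denominator", "percentage_display"]]
      .to_string(index=False))

sub = subgroup_table(data["likert"], data["roster"], keys=["arm"],
                     catalog=catalog)
print("\npooled agreement by study arm (1 = wristband only, 2 = +patch):")
print(sub.round(3).to_string(index=False))
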