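import dataclasses

import pandas as pd
import pytest

from wearcov import StudyDesign
from wearcov.synthetic_cohort import SyntheticConfig


@pytest.fixture
def small_design() -> StudyDesign:
    """One 21-day cycle of 10 participants (5 per arm) for fast tests."""
    return StudyDesign(n_cycles=1, participants_per_cycle=10,
                       arm1_per_cycle=5, arm2_per_cycle=5)


@pytest.fixture
def small_config(small_design) -> SyntheticConfig:
    return dataclasses.replace(SyntheticConfig(seed=11), design=small_design)


@pytest.fixture
def one_participant() -> pd.DataFrame:
    """Single-row roster with the standard 21-day window."""
    return pd.DataFrame([{
        "participant_id": "P001", "sex": "female", "age_years": 30,
        "arm": 2, "cycle": 1,
        "enrollment_start": pd.Timestamp("2021-01-18"),
        "enrollment_end": pd.Timestamp("2021-02-07"),
    }])


def participant_row(**overrides):
    """A lightweight participant object for direct simulator calls."""
    class Row:
        participant_id = "P001"
        sex = "female"
        age_years = 30
        arm = 2
        cycle = 1
        enrollment_start = pd.Timestamp("2021-01-18")
        enrollment_end = pd.Timestamp("2021-02-07")

    row = Row()
    for key, value in overrides.items():
        setattr(row, key, value)
    return row
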