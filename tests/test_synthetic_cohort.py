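import dataclasses

import numpy as np
import pandas as pd
import pytest

from wearcov import StudyDesign, default_stream_specs
from wearcov import synthetic_cohort as syn
from conftest import participant_row


def _rng(seed=0):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def test_cohort_counts_and_determinism():
    cfg = syn.SyntheticConfig(seed=4)
    roster = syn.generate_cohort(cfg)
    assert len(roster) == 150
    assert (roster["arm"] == 1).sum() == 81
    assert (roster["arm"] == 2).sum() == 69
    per_cycle = roster.groupby("cycle")["arm"].value_counts().unstack()
    assert (per_cycle[1] == 27).all() and (per_cycle[2] == 23).all()
    windows = roster.groupby("cycle")["enrollment_start"].first()
    assert (windows.diff().dropna() == pd.Timedelta(days=21)).all()
    again = syn.generate_cohort(cfg)
    pd.testing.assert_frame_equal(roster, again)


def test_cohort_age_distribution_median():
    medians = [syn.generate_cohort(syn.SyntheticConfig(seed=s))["age_years"].median()
               for s in range(20)]
    assert 20 <= np.mean(medians) <= 32
    ages = syn.generate_cohort(syn.SyntheticConfig(seed=0))["age_years"]
    assert ages.min() >= 6 and ages.max() <= 84


# ---------------------------------------------------------------------------
# wear sessions
# ---------------------------------------------------------------------------


def test_continuous_wear_limit_cases():
    cfg = dataclasses.replace(
        syn.SyntheticConfig(),
        wear=syn.WearConfig(daily_wear_prob=1.0, mean_gap_min=0.0))
    sessions = syn.simulate_wear_sessions(participant_row(arm=1), cfg, _rng())
    wrist = sessions[sessions["scope"] == "wrist"]
    assert len(wrist) == 21
    durations = (wrist["end"] - wrist["start"]).dt.total_seconds() / 60
    assert (durations == 1440).all()

    cfg0 = dataclasses.replace(cfg, wear=syn.WearConfig(daily_wear_prob=0.0))
    sessions = syn.simulate_wear_sessions(participant_row(arm=1), cfg0, _rng())
    assert sessions.empty


def test_renewal_long_run_wear_fraction():
    cfg = syn.SyntheticConfig()
    w = cfg.wear
    total, n_days = 0.0, 0
    for seed in range(5):
        sessions = syn.simulate_wear_sessions(participant_row(arm=1), cfg,
                                              _rng(seed))
        wrist = sessions[sessions["scope"] == "wrist"]
        total += (wrist["end"] - wrist["start"]).dt.total_seconds().sum() / 60
        n_days += 21
    frac = total / (n_days * 1440.0)
    expected = w.daily_wear_prob * w.mean_wear_bout_min / (
        w.mean_wear_bout_min + w.mean_gap_min)
    assert frac == pytest.approx(expected, abs=0.02)


def test_patch_sessions_only_arm2_non_overlapping():
    cfg = syn.SyntheticConfig()
    s1 = syn.simulate_wear_sessions(participant_row(arm=1), cfg, _rng(1))
    assert not s1["scope"].str.startswith("patch").any()
    cfg_all = dataclasses.replace(
        cfg, temperature=syn.TemperatureConfig(detach_prob_per_night=0.0))
    s2 = syn.simulate_wear_sessions(participant_row(arm=2), cfg_all, _rng(1))
    patch = s2[s2["scope"] == "patch"].sort_values("start")
    assert len(patch) == 21
    assert (patch["end"].to_numpy()[:-1] <= patch["start"].to_numpy()[1:]).all()


# ---------------------------------------------------------------------------
# streams
# ---------------------------------------------------------------------------


def test_stream_no_sessions_no_records():
    cfg = syn.SyntheticConfig()
    empty = pd.DataFrame(columns=["participant_id", "scope", "start", "end"])
    for stream in ("accelerometer", "heart_rate", "temperature"):
        out = syn.simulate_stream(participant_row(), empty,
                                  default_stream_specs()[stream], cfg, _rng())
        assert out.empty
    with pytest.raises(ValueError):
        dataclasses.replace(default_stream_specs()["heart_rate"], stream="ecg")


def test_heart_rate_full_day_certain_sampling():
    cfg = dataclasses.replace(
        syn.SyntheticConfig(),
        wear=syn.WearConfig(daily_wear_prob=1.0, mean_gap_min=0.0),
        heart=syn.HeartConfig(sample_success_prob=1.0))
    row = participant_row(arm=1)
    sessions = syn.simulate_wear_sessions(row, cfg, _rng())
    out = syn.simulate_stream(row, sessions, default_stream_specs()["heart_rate"],
                              cfg, _rng())
    # 1440 / 10 records per day over 21 days
    assert len(out) == 21 * 144


def test_heart_rate_sampling_rate_binomial():
    cfg = dataclasses.replace(
        syn.SyntheticConfig(),
        wear=syn.WearConfig(daily_wear_prob=1.0, mean_gap_min=0.0))
    p = cfg.heart.sample_success_prob
    row = participant_row(arm=1)
    n = emitted = 0
    for seed in range(10):
        sessions = syn.simulate_wear_sessions(row, cfg, _rng(seed))
        out = syn.simulate_stream(row, sessions,
                                  default_stream_specs()["heart_rate"], cfg,
                                  _rng(seed))
        emitted += len(out)
        n += 21 * 144
    se = np.sqrt(p * (1 - p) / n)
    assert emitted / n == pytest.approx(p, abs=3 * se)


def test_temperature_values_in_body_range():
    cfg = dataclasses.replace(
        syn.SyntheticConfig(),
        temperature=syn.TemperatureConfig(detach_prob_per_night=0.0))
    row = participant_row(arm=2)
    sessions = syn.simulate_wear_sessions(row, cfg, _rng(2))
    out = syn.simulate_stream(row, sessions, default_stream_specs()["temperature"],
                              cfg, _rng(2))
    t = cfg.temperature
    assert out["value"].between(t.body_mean_c - 6 * t.body_sd_c,
                                t.body_mean_c + 6 * t.body_sd_c).all()
    # one record per minute while attached
    minutes = (sessions.loc[sessions["scope"] == "patch", "end"]
               - sessions.loc[sessions["scope"] == "patch", "start"]
               ).dt.total_seconds().sum() / 60
    assert len(out) == pytest.approx(minutes, abs=len(sessions) + 1)


# ---------------------------------------------------------------------------
# attrition
# ---------------------------------------------------------------------------


def _study(cfg):
    return syn.simulate_study(cfg)


def test_sync_loss_identity_and_total_loss(small_config):
    clean = dataclasses.replace(
        small_config, attrition=syn.AttritionConfig(0.0, 0.0))
    data = _study(clean)
    n0 = len(data["measurements"])
    assert n0 > 0

    total = dataclasses.replace(
        small_config, attrition=syn.AttritionConfig(1.0, 0.0))
    data_total = _study(total)
    # only records after the final visit (day 20 end) survive
    rel_days = ((pd.to_datetime(data_total["measurements"]["timestamp"])
                 - pd.Timestamp("2021-01-18")).dt.total_seconds() / 86400)
    assert (rel_days >= 20).all()


def test_sync_retention_matches_closed_form(small_config):
    p = 0.5
    cfg = dataclasses.replace(small_config,
                              attrition=syn.AttritionConfig(p, 0.0))
    base = dataclasses.replace(small_config,
                               attrition=syn.AttritionConfig(0.0, 0.0))
    kept = total = 0
    for seed in range(6):
        c1 = dataclasses.replace(cfg, seed=seed)
        c0 = dataclasses.replace(base, seed=seed)
        m1 = _study(c1)["measurements"]
        m0 = _study(c0)["measurements"]
        in_blocks = ((pd.to_datetime(m0["timestamp"])
                      - pd.Timestamp("2021-01-18")).dt.total_seconds()
                     < 20 * 86400)
        kept_blocks = ((pd.to_datetime(m1["timestamp"])
                        - pd.Timestamp("2021-01-18")).dt.total_seconds()
                       < 20 * 86400)
        kept += kept_blocks.sum()
        total += in_blocks.sum()
    # records are retained in whole blocks; SE is over ~n_blocks draws
    n_blocks = 6 * 10 * 2 * 5  # seeds x participants x devices x visits
    se = np.sqrt(p * (1 - p) / n_blocks)
    assert kept / total == pytest.approx(1 - p, abs=3 * se + 0.02)


def test_censoring_monotonicity_under_coupled_seeds(small_config):
    counts = []
    for p_sync, hazard in [(0.0, 0.0), (0.3, 0.0), (0.3, 0.05), (0.8, 0.05)]:
        cfg = dataclasses.replace(
            small_config, attrition=syn.AttritionConfig(p_sync, hazard))
        counts.append(len(_study(cfg)["measurements"]))
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# questionnaires
# ---------------------------------------------------------------------------


def test_questionnaire_schedule_and_extremes(small_config):
    roster = syn.generate_cohort(small_config)
    likert, mc = syn.simulate_questionnaires(roster, small_config, _rng(0))
    per_part = likert.groupby("participant_id").size()
    assert (per_part == 17 * 5).all()

    sure = dataclasses.replace(small_config,
                               questionnaire=syn.QuestionnaireConfig(
                                   agreement_prob=1.0))
    likert, _ = syn.simulate_questionnaires(roster, sure, _rng(0))
    from wearcov import default_likert_catalog, positive_agreement
    ag = positive_agreement(likert, default_likert_catalog())
    assert (ag["agreement"] == 1.0).all()


def test_questionnaire_agreement_recovery(small_config):
    roster = syn.generate_cohort(small_config)
    cfg = dataclasses.replace(small_config,
                              questionnaire=syn.QuestionnaireConfig(
                                  agreement_prob=0.97))
    from wearcov import default_likert_catalog, positive_agreement
    means = []
    for seed in range(5):
        likert, _ = syn.simulate_questionnaires(roster, cfg, _rng(seed))
        ag = positive_agreement(likert, default_likert_catalog())
        means.append(ag["agreement"].mean())
    assert np.mean(means) == pytest.approx(0.97, abs=0.02)


# ---------------------------------------------------------------------------
# analytic expectations
# ---------------------------------------------------------------------------


def test_expected_coverage_limit_cases():
    specs = default_stream_specs()
    full = dataclasses.replace(
        syn.SyntheticConfig(),
        wear=syn.WearConfig(daily_wear_prob=1.0, mean_gap_min=0.0),
        heart=syn.HeartConfig(sample_success_prob=1.0),
        attrition=syn.AttritionConfig(0.0, 0.0))
    assert syn.expected_coverage(full, specs["heart_rate"]) == pytest.approx(1.0)

    none = dataclasses.replace(full, wear=syn.WearConfig(daily_wear_prob=0.0))
    assert syn.expected_coverage(none, specs["accelerometer"]) == 0.0
    assert syn.expected_coverage(none, specs["heart_rate"]) == 0.0

    no_patch = dataclasses.replace(
        full, temperature=syn.TemperatureConfig(detach_prob_per_night=1.0))
    assert syn.expected_coverage(no_patch, specs["temperature"]) == 0.0


def test_expected_coverage_matches_simulation_small_cohort(small_config):
    # the full-scale (150 x 21 d, 10 seed) recovery check lives in the
    # acceptance suite; this is a quick 2-seed sanity bound
    specs = default_stream_specs()
    sims = {s: [] for s in specs}
    from wearcov import daily_coverage_frame, participant_coverage, validate_records
    for seed in (0, 1):
        cfg = dataclasses.replace(small_config, seed=seed)
        data = _study(cfg)
        records, _ = validate_records(data["measurements"], data["roster"])
        daily = daily_coverage_frame(records, data["roster"], specs)
        part = participant_coverage(daily)
        for s in specs:
            sims[s].append(part.loc[part["stream"] == s, "coverage"].mean())
    for s in specs:
        exp = syn.expected_coverage(small_config, specs[s])
        assert np.mean(sims[s]) == pytest.approx(exp, abs=0.06)
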