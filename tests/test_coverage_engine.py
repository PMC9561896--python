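import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearcov import StreamSpec, default_stream_specs
from wearcov import coverage_engine as cov
from wearcov.core_model import Participant

DAY = pd.Timestamp("2021-01-18")
WINDOW = (DAY, DAY + pd.Timedelta(days=1))


def _ts(minutes):
    return DAY + pd.to_timedelta(minutes, unit="min")


# ---------------------------------------------------------------------------
# covered_minutes and its brute-force oracle
# ---------------------------------------------------------------------------


def test_covered_minutes_worked_example():
    # points at 0, 30, 200 min with 60-min tolerance: 30 + 60 + 60
    assert cov.covered_minutes(_ts([0, 30, 200]), WINDOW, 60) == 150.0
    assert cov.coverage_oracle(_ts([0, 30, 200]), WINDOW, 60) == 150.0


def test_covered_minutes_empty_and_dense():
    assert cov.covered_minutes(_ts([]), WINDOW, 60) == 0.0
    every_50 = _ts(np.arange(0, 1440, 50))
    assert cov.covered_minutes(every_50, WINDOW, 60) == 1440.0


def test_covered_minutes_rejects_unsorted():
    with pytest.raises(ValueError):
        cov.covered_minutes(_ts([30, 0]), WINDOW, 60)
    with pytest.raises(ValueError):
        cov.covered_minutes(_ts([0, 0]), WINDOW, 60)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.data())
def test_oracle_equivalence_property(data):
    n = data.draw(st.integers(0, 40))
    seconds = sorted(data.draw(
        st.sets(st.integers(0, 86399), min_size=n, max_size=n)))
    tol_s = data.draw(st.integers(1, 7200))
    ts = DAY + pd.to_timedelta(seconds, unit="s")
    fast = cov.covered_minutes(ts, WINDOW, tol_s / 60.0)
    slow = cov.coverage_oracle(ts, WINDOW, tol_s / 60.0)
    assert fast == pytest.approx(slow, abs=1e-9)


def test_covered_minutes_monotone_in_points_and_tolerance():
    rng = np.random.default_rng(3)
    pts = np.sort(rng.choice(86400, size=30, replace=False))
    base = cov.covered_minutes(DAY + pd.to_timedelta(pts, unit="s"), WINDOW, 20)
    extra = np.sort(np.append(pts, 40000)) if 40000 not in pts else pts
    assert cov.covered_minutes(DAY + pd.to_timedelta(extra, unit="s"),
                               WINDOW, 20) >= base
    assert cov.covered_minutes(DAY + pd.to_timedelta(pts, unit="s"),
                               WINDOW, 40) >= base


# ---------------------------------------------------------------------------
# daily coverage
# ---------------------------------------------------------------------------


def _participant(arm=2):
    return Participant("P001", "female", 30, arm, 1,
                       pd.Timestamp("2021-01-18"), pd.Timestamp("2021-02-07"))


def _records(stream, timestamps, value=1.0):
    return pd.DataFrame({
        "participant_id": "P001", "stream": stream,
        "timestamp": pd.to_datetime(timestamps), "value": value})


def test_daily_coverage_zero_records_gives_21_zero_days():
    spec = default_stream_specs()["heart_rate"]
    out = cov.daily_coverage(_records("heart_rate", []), spec, _participant())
    assert len(out) == 21
    assert (out["coverage"] == 0).all()


def test_daily_coverage_dense_heart_rate_is_complete():
    ts = pd.date_range("2021-01-18", "2021-02-08", freq="10min",
                       inclusive="left")
    spec = default_stream_specs()["heart_rate"]
    out = cov.daily_coverage(_records("heart_rate", ts), spec, _participant())
    assert out["coverage"].min() == 1.0


def test_daily_coverage_nightly_temperature_clamps_to_one():
    # patch worn 23:00-07:00 every night: 480 covered min + 5-min tail > 480
    ts = []
    for night in range(20):
        start = pd.Timestamp("2021-01-18 23:00") + pd.Timedelta(days=night)
        ts.extend(pd.date_range(start, start + pd.Timedelta(hours=8),
                                freq="1min", inclusive="left"))
    spec = default_stream_specs()["temperature"]
    out = cov.daily_coverage(_records("temperature", ts), spec, _participant())
    full_nights = out.iloc[1:20]  # days with a complete preceding morning
    assert (full_nights["coverage"] == 1.0).all()
    assert out["coverage"].between(0, 1).all()


def test_midnight_split_conserves_covered_minutes():
    rng = np.random.default_rng(11)
    seconds = np.sort(rng.choice(21 * 86400, size=300, replace=False))
    ts = pd.Timestamp("2021-01-18") + pd.to_timedelta(seconds, unit="s")
    spec = default_stream_specs()["accelerometer"]
    out = cov.daily_coverage(_records("accelerometer", ts), spec, _participant())
    whole = cov.covered_minutes(ts, (pd.Timestamp("2021-01-18"),
                                     pd.Timestamp("2021-02-08")),
                                spec.tolerance_min)
    assert out["covered_min"].sum() == pytest.approx(whole, abs=1e-6)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _daily_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "stream", "day",
                                       "covered_min", "denominator_min",
                                       "coverage"])


def _roster(n=2):
    return pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(1, n + 1)],
        "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
        "age_years": np.linspace(6, 84, n).astype(int),
        "arm": [1, 2] * (n // 2) + [1] * (n % 2),
        "cycle": 1,
        "enrollment_start": pd.Timestamp("2021-01-18"),
        "enrollment_end": pd.Timestamp("2021-02-07"),
    })


def test_aggregate_two_extreme_participants():
    day = pd.Timestamp("2021-01-18")
    daily = _daily_frame(
        [("P001", "heart_rate", day, 0.0, 1440.0, 0.0),
         ("P002", "heart_rate", day, 1440.0, 1440.0, 1.0)])
    roster = _roster(4)
    out = cov.aggregate_coverage(daily, roster)
    overall = out[out["group"] == "overall"].iloc[0]
    assert overall["mean_coverage"] == 0.5
    assert overall["max_coverage"] == 1.0
    assert overall["n_below_1pct"] == 1
    assert overall["n_participants"] == 2


def test_grouped_means_recompose_to_overall():
    rng = np.random.default_rng(5)
    roster = _roster(8)
    day = pd.Timestamp("2021-01-18")
    daily = _daily_frame([
        (pid, "accelerometer", day, float(c) * 1440, 1440.0, float(c))
        for pid, c in zip(roster["participant_id"], rng.random(8))])
    out = cov.aggregate_coverage(daily, roster, group_by=["sex"])
    overall = out[out["group"] == "overall"].iloc[0]
    sexes = out[out["group"] == "sex"]
    recomposed = ((sexes["mean_coverage"] * sexes["n_participants"]).sum()
                  / sexes["n_participants"].sum())
    assert recomposed == pytest.approx(overall["mean_coverage"], abs=1e-12)
    with pytest.raises(ValueError):
        cov.aggregate_coverage(daily, roster, group_by=["village"])


def test_weekly_trend_flat_and_constructed_dip():
    roster = _roster(2)
    days = pd.date_range("2021-01-18", periods=21)
    uniform = _daily_frame([
        (pid, "accelerometer", d, 720.0, 1440.0, 0.5)
        for pid in roster["participant_id"] for d in days])
    trend = cov.weekly_trend(uniform, roster)
    cells = trend[trend["cycle"] == 1]
    assert len(cells) == 3
    assert (cells["mean_coverage"] == 0.5).all()

    # coverage lost in week 3 (e.g. a failed final synchronization)
    lossy = uniform.copy()
    week3 = pd.to_datetime(lossy["day"]) >= days[14]
    lossy.loc[week3, "coverage"] = 0.05
    trend = cov.weekly_trend(lossy, roster)
    cells = trend[trend["cycle"] == 1].set_index("week_in_cycle")["mean_coverage"]
    assert cells[3] < cells[1] and cells[3] < cells[2]


# ---------------------------------------------------------------------------
# sensitivity grid
# ---------------------------------------------------------------------------


def test_sensitivity_single_default_setting_matches_aggregate():
    rng = np.random.default_rng(9)
    seconds = np.sort(rng.choice(21 * 86400, size=500, replace=False))
    ts = pd.Timestamp("2021-01-18") + pd.to_timedelta(seconds, unit="s")
    records = _records("heart_rate", ts)
    roster = _roster(1)
    specs = default_stream_specs()
    grid = cov.sensitivity_grid(records, roster, specs,
                                tolerance_grid={"heart_rate": [15.0]})
    daily = cov.daily_coverage_frame(records, roster,
                                     {"heart_rate": specs["heart_rate"]})
    part = cov.participant_coverage(daily)
    assert grid["mean_coverage"].iloc[0] == pytest.approx(
        part["coverage"].mean(), abs=1e-12)


def test_sensitivity_monotone_in_tolerance():
    rng = np.random.default_rng(13)
    seconds = np.sort(rng.choice(21 * 86400, size=400, replace=False))
    ts = pd.Timestamp("2021-01-18") + pd.to_timedelta(seconds, unit="s")
    records = _records("heart_rate", ts)
    grid = cov.sensitivity_grid(records, _roster(1), default_stream_specs(),
                                tolerance_grid={"heart_rate": [5.0, 15.0, 30.0, 60.0]})
    means = grid.sort_values("tolerance_min")["mean_coverage"].to_numpy()
    assert (np.diff(means) >= 0).all()
    with pytest.raises(ValueError):
        cov.sensitivity_grid(records, _roster(1), default_stream_specs(),
                             tolerance_grid={"heart_rate": [-5.0]})


def test_sensitivity_sleep_reference_full_night_wear():
    # full-night patch wear saturates both a 6-h and an 8-h reference
    ts = []
    for night in range(21):
        start = pd.Timestamp("2021-01-18 22:00") + pd.Timedelta(days=night)
        end = min(start + pd.Timedelta(hours=9),
                  pd.Timestamp("2021-02-08"))
        ts.extend(pd.date_range(start, end, freq="1min", inclusive="left"))
    records = _records("temperature", ts)
    roster = _roster(1).assign(arm=2)
    grid = cov.sensitivity_grid(records, roster, default_stream_specs(),
                                tolerance_grid={"temperature": [5.0]},
                                sleep_refs=[360.0, 480.0])
    assert (grid["mean_coverage"] > 0.97).all()
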