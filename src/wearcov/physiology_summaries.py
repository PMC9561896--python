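"""Plausibility filtering and descriptive physiology summaries.

Consumer wearables record physically impossible values when worn
incorrectly (most visibly, a detached thermometer patch logging ambient
room temperature), so summaries are computed only on records inside a
per-stream plausible keep-range; everything outside is flagged and kept
in a separate table, never silently deleted.  On top of the filtered
records this module builds daily activity/sleep/heart-rate summaries,
six-number quantile tables and hour-of-day (diurnal) profiles.

Step-to-distance and step-to-energy conversions are transparent linear
stand-ins (the vendor algorithms are undisclosed): metres per step plus a
basal daily energy expenditure with a per-step increment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlausibilityRule:
    """Keep-range (records outside are flagged) and informational
    normal range (``normal_range`` must sit inside ``keep_range``)."""

    stream: str
    keep_range: tuple[float, float]
    normal_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.keep_range
        if not lo < hi:
            raise ValueError("keep_range must satisfy low < high")
        if self.normal_range is not None:
            nlo, nhi = self.normal_range
            if not (lo <= nlo < nhi <= hi):
                raise ValueError("normal_range must lie inside keep_range")


def default_rules() -> dict[str, PlausibilityRule]:
    """Temperature keeps 34-41 °C (34-37 normal, up to 41 possibly
    feverish); heart rate keeps a wide 25-220 bpm band; step counts any
    non-negative epoch value."""
    return {
        "accelerometer": PlausibilityRule("accelerometer", (0.0, 50000.0)),
        "heart_rate": PlausibilityRule("heart_rate", (25.0, 220.0)),
        "temperature": PlausibilityRule("temperature", (34.0, 41.0), (34.0, 37.0)),
    }


@dataclass(frozen=True)
class ConversionFactors:
    """Linear step-derived quantities (vendor stand-ins)."""

    distance_m_per_step: float = 0.7
    kcal_basal_per_day: float = 778.0
    kcal_per_step: float = 0.064


def filter_plausible(records: pd.DataFrame,
                     rules: dict[str, PlausibilityRule]
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, int]]]:
    """Split records into kept (inside keep-range, bounds inclusive) and
    flagged, labelling each record's plausibility class.

    Temperature labels are tri-level inside the keep-range
    (``normal`` / ``feverish``) plus ``below_keep`` / ``above_keep``;
    other streams use ``in_range`` / ``below_keep`` / ``above_keep``.
    Kept + flagged always partition the input, per stream.
    """
    present = set(records["stream"].unique()) if len(records) else set()
    missing = present - set(rules)
    if missing:
        raise ValueError(f"no plausibility rule for streams {sorted(missing)}")
    if records.empty:
        empty = records.assign(plausibility=pd.Series(dtype=object))
        return empty, empty.copy(), {}

    df = records.copy()
    lo = df["stream"].map({s: r.keep_range[0] for s, r in rules.items()}).to_numpy()
    hi = df["stream"].map({s: r.keep_range[1] for s, r in rules.items()}).to_numpy()
    v = df["value"].to_numpy()
    label = np.where(v < lo, "below_keep", np.where(v > hi, "above_keep", "in_range"))
    for s, r in rules.items():
        if r.normal_range is None:
            continue
        m = (df["stream"] == s).to_numpy() & (label == "in_range")
        nlo, nhi = r.normal_range
        label = np.where(m & (v <= nhi) & (v >= nlo), "normal",
                         np.where(m, "feverish", label))
    df["plausibility"] = label
    keep = (v >= lo) & (v <= hi)
    kept = df[keep].reset_index(drop=True)
    flagged = df[~keep].reset_index(drop=True)
    counts = {
        s: {"kept": int((kept["stream"] == s).sum()),
            "flagged": int((flagged["stream"] == s).sum())}
        for s in sorted(present)
    }
    return kept, flagged, counts


def _night_date(ts: pd.Series) -> pd.Series:
    """Attribute a night-worn record to its wake date (records after noon
    belong to the following morning)."""
    t = pd.to_datetime(ts)
    return (t + pd.Timedelta(hours=12)).dt.normalize()


def daily_summary(records: pd.DataFrame, roster: pd.DataFrame,
                  conversion: ConversionFactors | None = None) -> pd.DataFrame:
    """One row per participant and enrolled day: steps, derived distance
    and energy, sleep hours, heart-rate statistics.

    ``steps`` sums the day's step-epoch values (0 if none); ``sleep_h``
    is the night-attributed thermometer wear time (the patch is worn only
    during sleep) and is absent without temperature data; heart-rate
    columns are absent on days without heart-rate records.  ``has_data``
    marks days with at least one record of any stream, letting callers
    mirror a vendor export that omits empty days.
    """
    conv = conversion or ConversionFactors()
    grid = []
    for row in roster.itertuples(index=False):
        n_days = (pd.Timestamp(row.enrollment_end)
                  - pd.Timestamp(row.enrollment_start)).days + 1
        grid.append(pd.DataFrame({
            "participant_id": row.participant_id,
            "date": pd.Timestamp(row.enrollment_start) + pd.to_timedelta(
                np.arange(n_days), unit="D"),
        }))
    out = pd.concat(grid, ignore_index=True)

    if len(records):
        df = records.copy()
        df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
        steps = (df[df["stream"] == "accelerometer"]
                 .groupby(["participant_id", "date"])["value"].sum()
                 .rename("steps"))
        hr = (df[df["stream"] == "heart_rate"]
              .groupby(["participant_id", "date"])["value"]
              .agg(hr_mean="mean", hr_min="min", hr_max="max"))
        temp = df[df["stream"] == "temperature"].copy()
        temp["date"] = _night_date(temp["timestamp"])
        cadence_min = 1.0  # thermometer emits one record per minute when worn
        sleep = (temp.groupby(["participant_id", "date"])["value"].size()
                 * cadence_min / 60.0).rename("sleep_h")
        any_rec = (df.groupby(["participant_id", "date"]).size() > 0).rename("has_data")
        for part in (steps, hr, sleep, any_rec):
            out = out.merge(part, on=["participant_id", "date"], how="left")
    else:
        out[["steps", "hr_mean", "hr_min", "hr_max", "sleep_h"]] = np.nan
        out["has_data"] = False

    out["steps"] = out["steps"].fillna(0.0)
    if "has_data" not in out.columns:
        out["has_data"] = False
    out["has_data"] = out["has_data"].eq(True)
    out["distance_m"] = out["steps"] * conv.distance_m_per_step
    out["kcal"] = conv.kcal_basal_per_day + out["steps"] * conv.kcal_per_step
    cols = ["participant_id", "date", "steps", "distance_m", "kcal",
            "sleep_h", "hr_mean", "hr_min", "hr_max", "has_data"]
    return out[cols]


def quantile_table(variables: dict[str, "pd.Series | np.ndarray"]) -> pd.DataFrame:
    """Six-number summary (min, Q1, median, mean, Q3, max) per variable.

    Quantiles use linear interpolation between order statistics; empty
    variables are omitted with a log line.
    """
    rows = []
    for name, values in variables.items():
        v = pd.Series(values).dropna().to_numpy(dtype=float)
        if v.size == 0:
            logger.warning("quantile_table: variable %r has no values, omitted", name)
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"variable": name, "min": v.min(), "q1": q1, "median": med,
                     "mean": v.mean(), "q3": q3, "max": v.max()})
    return pd.DataFrame(rows, columns=["variable", "min", "q1", "median",
                                       "mean", "q3", "max"])


def diurnal_profile(records: pd.DataFrame, value_mode: str = "steps_sum",
                    roster: pd.DataFrame | None = None,
                    strata: str | None = None) -> pd.DataFrame:
    """24-bin hour-of-day profile.

    ``steps_sum``: hourly step sums per participant-day (zero-filled over
    days that have any accelerometer data), averaged per participant and
    then across participants.  ``hr_mean``: mean over heart-rate records
    per hour bin.  Hour bins are closed-open [h, h+1) local time;
    ``strata="sex"`` stratifies via the roster.
    """
    if value_mode not in ("steps_sum", "hr_mean"):
        raise ValueError(f"unknown value_mode {value_mode!r}")
    stream = "accelerometer" if value_mode == "steps_sum" else "heart_rate"
    df = records[records["stream"] == stream].copy()
    df["hour"] = pd.to_datetime(df["timestamp"]).dt.hour
    if strata is not None:
        if roster is None:
            raise ValueError("strata requires a roster")
        df = df.merge(roster[["participant_id", strata]], on="participant_id",
                      how="left")
    keys = [strata] if strata else []

    hours = pd.DataFrame({"hour": np.arange(24)})
    if value_mode == "hr_mean":
        if df.empty:
            return pd.DataFrame(columns=keys + ["hour", "mean", "n"])
        g = df.groupby(keys + ["hour"], as_index=False)["value"].agg(
            mean="mean", n="size")
        return g[keys + ["hour", "mean", "n"]]

    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    if df.empty:
        return pd.DataFrame(columns=keys + ["hour", "mean", "n"])
    per_day = (df.groupby(["participant_id", "date", "hour"], as_index=False)
               ["value"].sum())
    # zero-fill missing hours within each observed participant-day
    days = per_day[["participant_id", "date"]].drop_duplicates()
    full = days.merge(hours, how="cross").merge(
        per_day, on=["participant_id", "date", "hour"], how="left")
    full["value"] = full["value"].fillna(0.0)
    per_part = (full.groupby(["participant_id", "hour"], as_index=False)["value"]
                .mean())
    if strata:
        per_part = per_part.merge(roster[["participant_id", strata]],
                                  on="participant_id", how="left")
    g = per_part.groupby(keys + ["hour"], as_index=False)["value"].agg(
        mean="mean", n="size")
    return g[keys + ["hour", "mean", "n"]]
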