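"""Domain types, CSV I/O, validation and study-design utilities.

The package analyses long-format wearable time series from a three-cycle
field deployment: a wrist tracker recording step counts (accelerometry) and
photoplethysmography heart rate, and for one study arm an axillary
thermometer patch worn at night.  This module holds the shared vocabulary
(streams, per-stream contracts, study design), the fixed CSV schemas, the
record validator, and two small design utilities: a Cochran sample-size
calculation with finite-population correction and quantile-based age
grouping.

All timestamps are naive local time (single site, no DST); a "day" is a
calendar day inside a participant's enrollment window.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STREAMS = ("accelerometer", "heart_rate", "temperature")

#: fixed long-format measurement schema (ISO 8601 local timestamps)
MEASUREMENT_COLUMNS = ["participant_id", "stream", "timestamp", "value"]
ROSTER_COLUMNS = [
    "participant_id",
    "sex",
    "age_years",
    "arm",
    "cycle",
    "enrollment_start",
    "enrollment_end",
]


class SchemaError(ValueError):
    """Input file header does not match the documented schema."""


class DegenerateGroupingError(ValueError):
    """Too few distinct ages to form four quantile groups."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StreamSpec:
    """Per-stream analysis contract.

    Parameters
    ----------
    stream:
        One of ``accelerometer``, ``heart_rate``, ``temperature``.
    tolerance_min:
        The epoch (minutes) one output data point is deemed to cover.
    cadence_min:
        Nominal output interval in minutes; ``None`` for event-driven
        output (the accelerometer emits values only during activity).
    denominator_mode:
        ``full_day`` (1440 min/day) or ``sleep_window`` (a reduced daily
        reference for devices worn only at night).
    sleep_ref_min:
        Daily reference duration in minutes for ``sleep_window`` mode.
    plausible_range:
        ``(low, high)`` physiologically plausible values in stream units.
    """

    stream: str
    tolerance_min: float
    cadence_min: float | None = None
    denominator_mode: str = "full_day"
    sleep_ref_min: float = 480.0
    plausible_range: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}")
        if self.tolerance_min <= 0:
            raise ValueError("tolerance_min must be > 0")
        if not (0 < self.sleep_ref_min <= 1440):
            raise ValueError("sleep_ref_min must be in (0, 1440]")
        if self.denominator_mode not in ("full_day", "sleep_window"):
            raise ValueError(f"unknown denominator_mode {self.denominator_mode!r}")
        if not self.plausible_range[0] < self.plausible_range[1]:
            raise ValueError("plausible_range must satisfy low < high")

    @property
    def denominator_min(self) -> float:
        return 1440.0 if self.denominator_mode == "full_day" else self.sleep_ref_min


def default_stream_specs() -> dict[str, StreamSpec]:
    """The study defaults: tolerances 60/15/5 min, 8-h sleep reference."""
    return {
        "accelerometer": StreamSpec(
            "accelerometer",
            tolerance_min=60.0,
            cadence_min=None,
            denominator_mode="full_day",
            plausible_range=(0.0, 50000.0),
        ),
        "heart_rate": StreamSpec(
            "heart_rate",
            tolerance_min=15.0,
            cadence_min=10.0,
            denominator_mode="full_day",
            plausible_range=(25.0, 220.0),
        ),
        "temperature": StreamSpec(
            "temperature",
            tolerance_min=5.0,
            cadence_min=1.0,
            denominator_mode="sleep_window",
            sleep_ref_min=480.0,
            plausible_range=(34.0, 41.0),
        ),
    }


@dataclass(frozen=True)
class StudyDesign:
    """Deployment design: three 21-day cycles of 50 participants each.

    Arm 1 (wristband only) has 27 participants per cycle, arm 2
    (wristband + thermometer patch) 23.  Field workers visit every 4 days
    to run the questionnaire and synchronize devices; the wristband
    buffers at most ``sync_buffer_days`` locally.
    """

    n_cycles: int = 3
    cycle_length_days: int = 21
    participants_per_cycle: int = 50
    arm1_per_cycle: int = 27
    arm2_per_cycle: int = 23
    visit_interval_days: int = 4
    questionnaires_per_cycle: int = 5
    sync_buffer_days: int = 5

    def __post_init__(self) -> None:
        if self.arm1_per_cycle + self.arm2_per_cycle != self.participants_per_cycle:
            raise ValueError("arm1_per_cycle + arm2_per_cycle must equal participants_per_cycle")
        for name in ("n_cycles", "cycle_length_days", "participants_per_cycle",
                     "visit_interval_days", "questionnaires_per_cycle"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def visit_days(self) -> list[int]:
        """1-indexed day numbers whose end has a field-worker visit."""
        return list(range(self.visit_interval_days, self.cycle_length_days,
                          self.visit_interval_days))


@dataclass(frozen=True)
class Participant:
    participant_id: str
    sex: str
    age_years: int
    arm: int
    cycle: int
    enrollment_start: pd.Timestamp
    enrollment_end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.age_years < 6:
            raise ValueError("age_years must be >= 6")
        if self.arm not in (1, 2):
            raise ValueError("arm must be 1 or 2")
        ndays = (self.enrollment_end - self.enrollment_start).days
        if ndays != 20:
            raise ValueError("enrollment window must span 21 calendar days")


@dataclass
class LoadReport:
    n_loaded: int = 0
    n_rejected: int = 0
    reject_reasons: dict[str, int] = field(default_factory=dict)


@dataclass
class ValidationReport:
    n_input: int = 0
    n_kept: int = 0
    n_duplicates: int = 0
    n_out_of_window: int = 0
    n_unknown_participant: int = 0
    n_arm1_temperature: int = 0
    per_stream_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_measurements(path: str | Path,
                      specs: dict[str, StreamSpec] | None = None
                      ) -> tuple[pd.DataFrame, LoadReport]:
    """Read a long-format measurement CSV.

    Malformed rows (unparseable timestamp, non-numeric value, unknown
    stream) are rejected and counted in the report, never silently
    dropped.  A missing or extra column raises :class:`SchemaError`.
    """
    raw = pd.read_csv(path, dtype=str)
    if list(raw.columns) != MEASUREMENT_COLUMNS and set(raw.columns) != set(MEASUREMENT_COLUMNS):
        raise SchemaError(
            f"expected columns {MEASUREMENT_COLUMNS}, found {list(raw.columns)}")
    raw = raw[MEASUREMENT_COLUMNS]
    report = LoadReport()
    known = set(specs) if specs is not None else set(STREAMS)

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    val = pd.to_numeric(raw["value"], errors="coerce")
    bad_ts = ts.isna()
    bad_val = val.isna()
    bad_stream = ~raw["stream"].isin(known)
    bad = bad_ts | bad_val | bad_stream
    report.reject_reasons = {
        "timestamp": int(bad_ts.sum()),
        "value": int((bad_val & ~bad_ts).sum()),
        "stream": int((bad_stream & ~bad_ts & ~bad_val).sum()),
    }
    report.n_rejected = int(bad.sum())
    if report.n_rejected:
        logger.warning("rejected %d malformed measurement rows: %s",
                       report.n_rejected, report.reject_reasons)
    out = pd.DataFrame({
        "participant_id": raw.loc[~bad, "participant_id"].astype(str),
        "stream": raw.loc[~bad, "stream"].astype(str),
        "timestamp": ts[~bad].dt.floor("s"),
        "value": val[~bad].astype(float),
    }).reset_index(drop=True)
    report.n_loaded = len(out)
    return out, report


def write_measurements(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the fixed long-format schema (ISO 8601 timestamps)."""
    out = records[MEASUREMENT_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False)


def load_roster(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if set(df.columns) != set(ROSTER_COLUMNS):
        raise SchemaError(f"expected columns {ROSTER_COLUMNS}, found {list(df.columns)}")
    df = df[ROSTER_COLUMNS].copy()
    for col in ("enrollment_start", "enrollment_end"):
        df[col] = pd.to_datetime(df[col])
    df["arm"] = df["arm"].astype(int)
    df["cycle"] = df["cycle"].astype(int)
    df["age_years"] = df["age_years"].astype(int)
    return df


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    out = roster[ROSTER_COLUMNS].copy()
    for col in ("enrollment_start", "enrollment_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_records(records: pd.DataFrame, roster: pd.DataFrame,
                     drop_arm1_temperature: bool = False
                     ) -> tuple[pd.DataFrame, ValidationReport]:
    """Clean a measurement table against the participant roster.

    Removes records for unknown participants and records outside the
    participant's enrollment window, collapses duplicates on
    (participant, stream, timestamp), and flags temperature records for
    arm-1 participants (who carried no patch).  The operation is
    idempotent and invariant to the input row order: ties are broken on
    the full row, and the output is sorted by participant, stream and
    timestamp.
    """
    if roster.empty:
        raise ValueError("roster must be non-empty")
    report = ValidationReport(n_input=len(records))
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    meta = roster.set_index("participant_id")[["arm", "enrollment_start", "enrollment_end"]]
    known = df["participant_id"].isin(meta.index)
    report.n_unknown_participant = int((~known).sum())
    df = df[known]

    start = meta["enrollment_start"].reindex(df["participant_id"]).to_numpy()
    end = (meta["enrollment_end"].reindex(df["participant_id"])
           + pd.Timedelta(days=1)).to_numpy()
    ts = df["timestamp"].to_numpy()
    in_window = (ts >= start) & (ts < end)
    report.n_out_of_window = int((~in_window).sum())
    df = df[in_window]

    df = df.sort_values(MEASUREMENT_COLUMNS, kind="mergesort")
    dup = df.duplicated(subset=["participant_id", "stream", "timestamp"], keep="first")
    report.n_duplicates = int(dup.sum())
    df = df[~dup]

    arm = meta["arm"].reindex(df["participant_id"]).to_numpy()
    arm1_temp = (arm == 1) & (df["stream"] == "temperature").to_numpy()
    report.n_arm1_temperature = int(arm1_temp.sum())
    if report.n_arm1_temperature:
        logger.warning("found %d temperature records for arm-1 participants",
                       report.n_arm1_temperature)
        if drop_arm1_temperature:
            df = df[~arm1_temp]

    df = df.reset_index(drop=True)
    report.n_kept = len(df)
    report.per_stream_counts = df["stream"].value_counts().to_dict()
    return df, report


# ---------------------------------------------------------------------------
# study-design utilities
# ---------------------------------------------------------------------------


def sample_size_fpc(population: int, confidence: float = 0.95,
                    margin: float = 0.08, proportion: float = 0.5) -> int:
    """Cochran sample size for a proportion with finite-population correction.

    n0 = z^2 p (1-p) / e^2, corrected as n0 / (1 + (n0 - 1)/N) and rounded
    up.  With N = 100,000, 95% confidence and an 8% margin this gives the
    study's n = 150.
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    if not (0 < margin < 1):
        raise ValueError("margin must be in (0, 1)")
    if not (0 < proportion < 1):
        raise ValueError("proportion must be in (0, 1)")
    if population < 1:
        raise ValueError("population must be >= 1")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n0 = z * z * proportion * (1.0 - proportion) / (margin * margin)
    n = n0 / (1.0 + (n0 - 1.0) / population)
    return int(math.ceil(n - 1e-12))


def assign_age_groups(ages) -> tuple[np.ndarray, list[int]]:
    """Split ages into four quantile groups (25th/50th/75th percentiles).

    Percentiles use linear interpolation between order statistics; cut
    points are floored to whole years so labels read e.g. ``6-16``,
    ``17-26``, ``27-42``, ``43-84``.  Intervals are half-open on the
    right except the last, so every age maps to exactly one group.

    Returns (label per input age, the three integer cut points).
    """
    arr = np.asarray(ages, dtype=float)
    if arr.size == 0 or np.unique(arr).size < 4:
        raise DegenerateGroupingError("need at least 4 distinct ages for quartile groups")
    cuts = [int(math.floor(q)) for q in np.percentile(arr, [25, 50, 75])]
    lo, hi = int(math.floor(arr.min())), int(math.ceil(arr.max()))
    if not (lo <= cuts[0] < cuts[1] < cuts[2] < hi):
        raise DegenerateGroupingError(
            f"quartile cut points {cuts} do not split the age range [{lo}, {hi}]")
    labels = [
        f"{lo}-{cuts[0]}",
        f"{cuts[0] + 1}-{cuts[1]}",
        f"{cuts[1] + 1}-{cuts[2]}",
        f"{cuts[2] + 1}-{hi}",
    ]
    idx = np.searchsorted(cuts, arr, side="left")
    return np.array(labels, dtype=object)[idx], cuts


def age_group_column(roster: pd.DataFrame) -> pd.Series:
    labels, _ = assign_age_groups(roster["age_years"].to_numpy())
    return pd.Series(labels, index=roster.index, name="age_group")


def config_hash(obj) -> str:
    """Stable hash of a (nested-dataclass) configuration for run logs."""
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, (list, tuple)):
            return [enc(x) for x in o]
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        return o
    return hashlib.sha256(json.dumps(enc(obj), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Run simulate -> validate -> coverage -> physiology -> acceptability.

    Writes all output tables as CSV into ``out_dir`` together with a run
    log (seed, config hash, package versions).  Any stage failure aborts
    with a stage-named error; a partial run leaves a ``RUN_INCOMPLETE``
    marker in the directory.

    ``config`` is a :class:`~wearcov.synthetic_cohort.SyntheticConfig`
    (optionally with an ``analysis`` attribute, see :func:`load_config`).
    Returns a mapping of table name -> written path.
    """
    from . import acceptability_analysis as acc
    from . import coverage_engine as cov
    from . import physiology_summaries as phys
    from . import synthetic_cohort as syn

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "RUN_INCOMPLETE"
    marker.write_text("pipeline started\n")
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    analysis = getattr(config, "analysis", None) or AnalysisOptions()
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, float_cols: tuple[str, ...] = ()) -> None:
        path = out / f"{name}.csv"
        df = df.copy()
        for col in float_cols:
            if col in df.columns:
                df[col] = df[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d %H:%M:%S")
        df.to_csv(path, index=False)
        written[name] = path

    stage = "simulate"
    try:
        data = syn.simulate_study(config)
        write_roster(data["roster"], out / "roster.csv")
        write_measurements(data["measurements"], out / "measurements.csv")
        data["likert"].to_csv(out / "likert_responses.csv", index=False)
        data["mc"].to_csv(out / "mc_responses.csv", index=False)
        written.update({k: out / f"{k}.csv"
                        for k in ("roster", "measurements", "likert_responses", "mc_responses")})

        stage = "validate"
        specs = default_stream_specs()
        records, vreport = validate_records(data["measurements"], data["roster"])

        stage = "coverage"
        daily = cov.daily_coverage_frame(records, data["roster"], specs)
        emit("coverage_daily", daily, ("coverage",))
        part = cov.participant_coverage(daily)
        emit("coverage_participant", part, ("coverage",))
        summary = cov.aggregate_coverage(
            daily, data["roster"], group_by=["sex", "age_group", "arm", "cycle"])
        emit("coverage_summary", summary, ("mean_coverage", "max_coverage"))
        trend = cov.weekly_trend(daily, data["roster"], config.design)
        emit("weekly_trend", trend, ("mean_coverage",))
        grid = cov.sensitivity_grid(records, data["roster"], specs,
                                    analysis.tolerance_grid, analysis.sleep_refs)
        emit("sensitivity_grid", grid, ("mean_coverage",))

        stage = "physiology"
        kept, flagged, _ = phys.filter_plausible(records, phys.default_rules())
        emit("flagged_records", flagged)
        daily_sum = phys.daily_summary(kept, data["roster"])
        emit("daily_summary", daily_sum)
        observed = daily_sum[daily_sum["has_data"]]
        qt = phys.quantile_table({
            "heart_rate_bpm": kept.loc[kept["stream"] == "heart_rate", "value"],
            "kcal_per_day": observed["kcal"],
            "steps_per_day": observed["steps"],
            "distance_m_per_day": observed["distance_m"],
            "sleep_h_per_day": observed["sleep_h"].dropna(),
            "temperature_c": kept.loc[kept["stream"] == "temperature", "value"],
        })
        emit("quantile_table", qt)
        profile = phys.diurnal_profile(kept, value_mode="steps_sum", roster=data["roster"],
                                       strata="sex")
        emit("diurnal_profile", profile, ("mean",))

        stage = "acceptability"
        catalog = acc.default_likert_catalog()
        agreements = acc.positive_agreement(data["likert"], catalog)
        emit("agreement_items", agreements, ("agreement",))
        cat = acc.category_summary(agreements, catalog, threshold=analysis.agreement_threshold)
        emit("category_summary", cat, ("mean_agreement", "min_agreement", "max_agreement"))
        mc = acc.tabulate_mc(data["mc"], acc.default_mc_catalog(),
                             denominator_policy=analysis.denominator_policy)
        emit("mc_tables", mc, ("percentage",))
        sub = acc.subgroup_table(data["likert"], data["roster"],
                                 keys=["sex", "age_group", "arm", "cycle"], catalog=catalog)
        emit("subgroup_tables", sub, ("metric",))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    import wearcov

    log = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "versions": {"wearcov": wearcov.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "validation": dataclasses.asdict(vreport),
        "tables": sorted(written),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    marker.unlink()
    return written


@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis-stage knobs for :func:`run_pipeline`.

    The default sensitivity grids bracket the study tolerances and the
    8-h sleep reference.
    """

    tolerance_grid: dict = field(default_factory=lambda: {
        "accelerometer": [30.0, 60.0, 90.0],
        "heart_rate": [10.0, 15.0, 30.0],
        "temperature": [5.0, 10.0, 15.0],
    })
    sleep_refs: tuple[float, ...] = (360.0, 420.0, 480.0, 540.0)
    agreement_threshold: float = 0.9
    denominator_policy: str = "respondents"


def load_config(path: str | Path):
    """Load a YAML pipeline configuration.

    The file mirrors the SyntheticConfig / StudyDesign / AnalysisOptions
    field structure; unknown keys raise, so typos do not silently fall
    back to defaults.
    """
    import yaml

    from . import synthetic_cohort as syn

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return syn.config_from_dict(data)
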