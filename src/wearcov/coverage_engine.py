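"""Epoch-tolerance data coverage.

A consumer wearable emits sparse, preprocessed output; to quantify how
much of the deployment it actually covered, each output data point is
deemed to cover a stream-specific tolerance epoch going forward (60 min
for accelerometry, 15 min for heart rate, 5 min for thermometer
readings).  Coverage of a reference window is the covered time divided by
a denominator: the full day (1440 min), or a reduced sleep reference
(default 8 h) for the patch worn only at night, with the ratio clamped to
[0, 1].

Covered time is computed as the sum over points of
``min(tolerance, gap to the next point or window end)``; the interval
before the first point is uncovered.  This covered-time formulation
equals the summed-gap-excess formulation on a full-day denominator and
stays well-defined for reduced denominators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_model import StreamSpec, StudyDesign, age_group_column, default_stream_specs

logger = logging.getLogger(__name__)

_DAY_S = 86400


def _to_seconds(ts) -> np.ndarray:
    arr = pd.to_datetime(pd.Series(np.asarray(ts)))
    return arr.astype("datetime64[s]").astype("int64").to_numpy()


def _tol_seconds(tolerance_min: float) -> float:
    """Tolerance in seconds, snapped to a whole second when the input is
    one (guards < / <= boundaries against float noise)."""
    tol_s = tolerance_min * 60.0
    return round(tol_s) if abs(tol_s - round(tol_s)) < 1e-6 else tol_s


def covered_minutes(timestamps, window, tolerance_min: float) -> float:
    """Minutes of ``window`` covered by ``timestamps`` under the tolerance.

    ``timestamps`` must be sorted, deduplicated and inside
    ``window = (start, end)``; each point covers forward
    ``min(tolerance, gap to next point or window end)``.  Empty input
    covers nothing.
    """
    start_s, end_s = (_to_seconds([window[0]])[0], _to_seconds([window[1]])[0])
    ts = _to_seconds(timestamps)
    if ts.size == 0:
        return 0.0
    if np.any(np.diff(ts) <= 0):
        raise ValueError("timestamps must be sorted and deduplicated")
    if ts[0] < start_s or ts[-1] >= end_s:
        raise ValueError("timestamps must lie inside the window [start, end)")
    tol_s = _tol_seconds(tolerance_min)
    gaps = np.diff(np.append(ts, end_s))
    return float(np.minimum(gaps, tol_s).sum() / 60.0)


def coverage_oracle(timestamps, window, tolerance_min: float,
                    grid_resolution_s: int = 1) -> float:
    """Brute-force grid oracle for :func:`covered_minutes`.

    Marks each grid second ``s`` covered iff a measurement exists in
    ``(s - tolerance, s]`` and returns marked seconds / 60.  At 1-s
    resolution with whole-second timestamps this agrees exactly with
    :func:`covered_minutes`.
    """
    if 60 % grid_resolution_s != 0:
        raise ValueError("grid_resolution_s must divide 60")
    start_s, end_s = (_to_seconds([window[0]])[0], _to_seconds([window[1]])[0])
    ts = np.sort(_to_seconds(timestamps))
    grid = np.arange(start_s, end_s, grid_resolution_s)
    if ts.size == 0 or grid.size == 0:
        return 0.0
    idx = np.searchsorted(ts, grid, side="right")
    prev = np.where(idx > 0, ts[np.maximum(idx - 1, 0)], np.iinfo(np.int64).min)
    covered = (idx > 0) & (grid - prev < _tol_seconds(tolerance_min))
    return float(covered.sum() * grid_resolution_s / 60.0)


# ---------------------------------------------------------------------------
# daily coverage
# ---------------------------------------------------------------------------


def daily_coverage_frame(records: pd.DataFrame, roster: pd.DataFrame,
                         specs: dict[str, StreamSpec] | None = None) -> pd.DataFrame:
    """Per participant/stream/enrolled-day covered minutes and coverage.

    One row per enrolled calendar day and applicable stream (temperature
    only for arm-2 participants); days without records get coverage 0.
    Covered intervals spanning midnight are split so per-day covered
    minutes sum exactly to the undivided whole-window value.  The
    ``coverage`` column is clamped to [0, 1]; ``covered_min`` is not.
    """
    specs = specs or default_stream_specs()
    meta = roster.set_index("participant_id")
    start_by_pid = meta["enrollment_start"]

    frames: list[pd.DataFrame] = []
    if not records.empty:
        df = records.sort_values(["participant_id", "stream", "timestamp"],
                                 kind="mergesort")
        ts = _to_seconds(df["timestamp"])
        pid = df["participant_id"].to_numpy()
        stream = df["stream"].to_numpy()
        same = np.empty(len(df), dtype=bool)
        if len(df):
            same[:-1] = (pid[:-1] == pid[1:]) & (stream[:-1] == stream[1:])
            same[-1] = False
        nxt = np.empty(len(df), dtype=np.int64)
        if len(df):
            nxt[:-1] = ts[1:]
        # last record of each group covers up to the enrollment-window end
        n_days = ((pd.to_datetime(meta["enrollment_end"])
                   - pd.to_datetime(meta["enrollment_start"])).dt.days + 1)
        win_end = (_to_seconds(start_by_pid.reindex(pid).to_numpy())
                   + n_days.reindex(pid).to_numpy() * _DAY_S)
        nxt[~same] = win_end[~same]
        tol_s = np.array([specs[s].tolerance_min * 60.0 for s in stream])
        cover = np.minimum(np.minimum(nxt - ts, tol_s), win_end - ts)
        cover = np.maximum(cover, 0)

        # split covered intervals at midnight (an interval spans at most
        # ceil(tol/1440)+1 days; loop until fully allocated)
        seg_start, seg_len = ts.astype(float), cover.astype(float)
        pid_seg, stream_seg = pid, stream
        while len(seg_start):
            day = (seg_start // _DAY_S).astype(np.int64)
            day_end = (day + 1) * _DAY_S
            take = np.minimum(seg_len, day_end - seg_start)
            frames.append(pd.DataFrame({
                "participant_id": pid_seg, "stream": stream_seg,
                "day_s": day * _DAY_S, "covered_s": take}))
            rest = seg_len - take
            keep = rest > 0
            seg_start = day_end[keep].astype(float)
            seg_len = rest[keep]
            pid_seg, stream_seg = pid_seg[keep], stream_seg[keep]

    if frames:
        per_day = (pd.concat(frames)
                   .groupby(["participant_id", "stream", "day_s"], as_index=False)
                   ["covered_s"].sum())
    else:
        per_day = pd.DataFrame(columns=["participant_id", "stream", "day_s", "covered_s"])

    # full participant x stream x enrolled-day grid
    grid_rows = []
    for row in roster.itertuples(index=False):
        streams = [s for s in specs
                   if not (s == "temperature" and row.arm == 1)]
        n_days = (pd.Timestamp(row.enrollment_end)
                  - pd.Timestamp(row.enrollment_start)).days + 1
        start_s = _to_seconds([row.enrollment_start])[0]
        for s in streams:
            grid_rows.append(pd.DataFrame({
                "participant_id": row.participant_id,
                "stream": s,
                "day_s": start_s + np.arange(n_days) * _DAY_S,
            }))
    grid = pd.concat(grid_rows, ignore_index=True)

    out = grid.merge(per_day, on=["participant_id", "stream", "day_s"], how="left")
    n_matched = int(out["covered_s"].notna().sum())
    if len(per_day) and n_matched < len(per_day):
        logger.warning("%d covered day-cells outside the applicable grid were excluded",
                       len(per_day) - n_matched)
    out["covered_s"] = out["covered_s"].astype(float).fillna(0.0)
    out["covered_min"] = out["covered_s"] / 60.0
    out["denominator_min"] = [specs[s].denominator_min for s in out["stream"]]
    out["coverage"] = np.clip(out["covered_min"] / out["denominator_min"], 0.0, 1.0)
    out["day"] = pd.to_datetime(out["day_s"], unit="s")
    return out[["participant_id", "stream", "day", "covered_min",
                "denominator_min", "coverage"]]


def daily_coverage(records: pd.DataFrame, spec: StreamSpec,
                   participant) -> pd.DataFrame:
    """Single-participant, single-stream convenience wrapper."""
    roster = pd.DataFrame([{
        "participant_id": participant.participant_id,
        "sex": participant.sex, "age_years": participant.age_years,
        "arm": participant.arm, "cycle": participant.cycle,
        "enrollment_start": pd.Timestamp(participant.enrollment_start),
        "enrollment_end": pd.Timestamp(participant.enrollment_end),
    }])
    recs = records[(records["participant_id"] == participant.participant_id)
                   & (records["stream"] == spec.stream)]
    out = daily_coverage_frame(recs, roster, {spec.stream: spec})
    return out[out["stream"] == spec.stream].reset_index(drop=True)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def participant_coverage(daily: pd.DataFrame) -> pd.DataFrame:
    """Participant-level coverage pooling minutes over enrolled days.

    coverage = min(1, sum covered / sum denominator); pooling minutes
    (rather than averaging daily ratios) is robust to clamped days.
    """
    g = daily.groupby(["participant_id", "stream"], as_index=False).agg(
        covered_min=("covered_min", "sum"),
        denominator_min=("denominator_min", "sum"),
        n_days=("day", "count"))
    g["coverage"] = np.clip(g["covered_min"] / g["denominator_min"], 0.0, 1.0)
    return g


_GROUP_KEYS = ("stream", "sex", "age_group", "arm", "cycle", "week_in_cycle", "overall")


def aggregate_coverage(daily: pd.DataFrame, roster: pd.DataFrame,
                       group_by: list[str] | None = None) -> pd.DataFrame:
    """Coverage summaries (mean, max, <1% count) per grouping.

    Emits the overall per-stream summary plus one block per requested
    key; participants with pooled coverage strictly below 1% are counted
    in ``n_below_1pct``.
    """
    group_by = list(group_by or [])
    for key in group_by:
        if key not in _GROUP_KEYS:
            raise ValueError(f"unknown grouping key {key!r}")
    part = participant_coverage(daily)
    meta = roster[["participant_id", "sex", "arm", "cycle"]].copy()
    meta["age_group"] = age_group_column(roster)
    part = part.merge(meta, on="participant_id", how="left")

    def summarize(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        g = df.groupby(keys, as_index=False, observed=True).agg(
            mean_coverage=("coverage", "mean"),
            max_coverage=("coverage", "max"),
            n_below_1pct=("coverage", lambda c: int((c < 0.01).sum())),
            n_participants=("coverage", "size"))
        return g

    blocks = [summarize(part, ["stream"]).assign(group="overall", level="all")]
    for key in group_by:
        if key in ("overall",):
            continue
        blk = summarize(part, ["stream", key]).rename(columns={key: "level"})
        blk["group"] = key
        blocks.append(blk)
    out = pd.concat(blocks, ignore_index=True)
    out["level"] = out["level"].astype(str)
    return out[["stream", "group", "level", "mean_coverage", "max_coverage",
                "n_below_1pct", "n_participants"]]


def weekly_trend(daily: pd.DataFrame, roster: pd.DataFrame,
                 design: StudyDesign | None = None) -> pd.DataFrame:
    """Mean daily coverage per (stream, cycle, week-in-cycle) cell.

    Weeks are fixed 7-day blocks from each cycle's start date
    (days 1-7, 8-14, 15-21).
    """
    design = design or StudyDesign()
    meta = roster.set_index("participant_id")[["cycle", "enrollment_start"]]
    df = daily.merge(meta, left_on="participant_id", right_index=True, how="left")
    offset = (pd.to_datetime(df["day"]) - pd.to_datetime(df["enrollment_start"])).dt.days
    df["week_in_cycle"] = (offset // 7 + 1).clip(
        upper=(design.cycle_length_days + 6) // 7)
    per_cycle = df.groupby(["stream", "cycle", "week_in_cycle"], as_index=False).agg(
        mean_coverage=("coverage", "mean"), n_days=("coverage", "size"))
    per_week = df.groupby(["stream", "week_in_cycle"], as_index=False).agg(
        mean_coverage=("coverage", "mean"), n_days=("coverage", "size"))
    per_week["cycle"] = 0  # 0 marks the all-cycle row
    return pd.concat([per_cycle, per_week], ignore_index=True)[
        ["stream", "cycle", "week_in_cycle", "mean_coverage", "n_days"]]


def sensitivity_grid(records: pd.DataFrame, roster: pd.DataFrame,
                     specs: dict[str, StreamSpec] | None = None,
                     tolerance_grid: dict[str, list[float]] | None = None,
                     sleep_refs: list[float] | None = None) -> pd.DataFrame:
    """Overall mean coverage for each tolerance / sleep-reference setting.

    Long-format table: one row per (stream, tolerance, sleep reference);
    sleep references only vary for sleep-window streams.
    """
    import dataclasses as _dc

    specs = specs or default_stream_specs()
    tolerance_grid = tolerance_grid or {s: [sp.tolerance_min] for s, sp in specs.items()}
    sleep_refs = list(sleep_refs or [])
    rows = []
    for stream, tols in tolerance_grid.items():
        base = specs[stream]
        for tol in tols:
            if tol <= 0:
                raise ValueError("tolerance must be positive")
            refs = (sleep_refs or [base.sleep_ref_min]) \
                if base.denominator_mode == "sleep_window" else [base.sleep_ref_min]
            for ref in refs:
                spec = _dc.replace(base, tolerance_min=float(tol),
                                   sleep_ref_min=float(ref))
                daily = daily_coverage_frame(
                    records[records["stream"] == stream], roster, {stream: spec})
                part = participant_coverage(daily)
                rows.append({
                    "stream": stream,
                    "tolerance_min": float(tol),
                    "sleep_ref_min": float(ref) if base.denominator_mode == "sleep_window"
                    else np.nan,
                    "mean_coverage": float(part["coverage"].mean()),
                    "n_participants": int(len(part)),
                })
    return pd.DataFrame(rows)
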