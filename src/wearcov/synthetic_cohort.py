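"""Synthetic cohort and multi-stream wearable data generator.

Since the field dataset is confidential, this module generates a cohort
with the study's structure (three 21-day cycles, 27 wristband-only and 23
wristband+patch participants each) and wearable output with its three
missingness mechanisms:

* **non-wear** -- per day a participant wears the wristband with
  probability ``daily_wear_prob``; within a wear day, wear follows a
  stationary alternating renewal process of exponential bouts and gaps.
  The patch is worn (or not) per night.
* **sync-buffer loss** -- at each 4-day field-worker visit the device
  buffer since the previous visit is lost with some probability; the
  partial block after the final visit is read out at device return and
  always survives.
* **device failure** -- a per-device geometric failure day censors all
  later records from that device.

Activity output is epoch step counts emitted only while active, so
inactivity and non-wear are indistinguishable in the output, as with the
real device; the latent wear sessions are returned separately as truth
for recovery tests only.  :func:`expected_coverage` gives an analytic
(renewal-theory) expectation of pipeline coverage per stream,
deliberately independent of the simulation code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import AnalysisOptions, StreamSpec, StudyDesign, default_stream_specs

_DAY_MIN = 1440.0
BASE_START = pd.Timestamp("2021-01-18")  # first cycle start

WRIST_STREAMS = ("accelerometer", "heart_rate")
DEVICE_OF_STREAM = {"accelerometer": "wristband", "heart_rate": "wristband",
                    "temperature": "patch"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _parse_clock(t: str) -> float:
    """'HH:MM' -> minutes after midnight."""
    h, m = t.split(":")
    return int(h) * 60.0 + int(m)


@dataclass(frozen=True)
class WearConfig:
    daily_wear_prob: float = 0.95
    mean_wear_bout_min: float = 300.0
    mean_gap_min: float = 60.0


@dataclass(frozen=True)
class SleepConfig:
    bedtime_mean: str = "22:30"
    bedtime_sd_min: float = 30.0
    wake_mean: str = "07:00"
    wake_sd_min: float = 30.0


@dataclass(frozen=True)
class ActivityConfig:
    base_steps_per_hour: float = 800.0
    midday_dip_factor: float = 0.6
    night_steps_per_hour: float = 0.05
    epoch_min: float = 30.0
    day_start_hour: int = 7
    day_end_hour: int = 22
    dip_start_hour: int = 12
    dip_end_hour: int = 18


@dataclass(frozen=True)
class HeartConfig:
    rest_bpm_mean: float = 73.0
    rest_bpm_sd: float = 8.0
    activity_coupling: float = 0.3       # bpm per (step/min)
    diurnal_amp_bpm: float = 4.0
    diurnal_peak_hour: float = 13.0
    sample_success_prob: float = 0.05    # PPG reads fail often in the field


@dataclass(frozen=True)
class TemperatureConfig:
    body_mean_c: float = 35.5
    body_sd_c: float = 0.5
    ambient_mean_c: float = 31.0
    ambient_sd_c: float = 0.8
    detach_prob_per_night: float = 0.9
    record_when_detached: bool = False


@dataclass(frozen=True)
class AttritionConfig:
    sync_failure_prob_per_visit: float = 0.35
    device_failure_hazard_per_day: float = 0.002


@dataclass(frozen=True)
class QuestionnaireConfig:
    #: overrides every item's agreement probability when set
    agreement_prob: float | None = None
    visits: int = 5


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    wear: WearConfig = field(default_factory=WearConfig)
    sleep: SleepConfig = field(default_factory=SleepConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    heart: HeartConfig = field(default_factory=HeartConfig)
    temperature: TemperatureConfig = field(default_factory=TemperatureConfig)
    attrition: AttritionConfig = field(default_factory=AttritionConfig)
    questionnaire: QuestionnaireConfig = field(default_factory=QuestionnaireConfig)
    analysis: AnalysisOptions | None = None

    def __post_init__(self) -> None:
        probs = [
            ("wear.daily_wear_prob", self.wear.daily_wear_prob),
            ("heart.sample_success_prob", self.heart.sample_success_prob),
            ("temperature.detach_prob_per_night", self.temperature.detach_prob_per_night),
            ("attrition.sync_failure_prob_per_visit",
             self.attrition.sync_failure_prob_per_visit),
            ("attrition.device_failure_hazard_per_day",
             self.attrition.device_failure_hazard_per_day),
        ]
        for name, p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name, r in [("wear.mean_wear_bout_min", self.wear.mean_wear_bout_min),
                        ("wear.mean_gap_min", self.wear.mean_gap_min),
                        ("activity.base_steps_per_hour", self.activity.base_steps_per_hour),
                        ("activity.night_steps_per_hour", self.activity.night_steps_per_hour)]:
            if r < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.activity.midday_dip_factor <= 1.0):
            raise ValueError("activity.midday_dip_factor must be in (0, 1]")
        bed = _parse_clock(self.sleep.bedtime_mean)
        wake = _parse_clock(self.sleep.wake_mean)
        if not wake < bed:  # bedtime precedes wake modulo midnight
            raise ValueError("expected wake before bedtime on the clock "
                             "(night spans midnight)")


_SECTION_TYPES = {
    "design": StudyDesign, "wear": WearConfig, "sleep": SleepConfig,
    "activity": ActivityConfig, "heart": HeartConfig,
    "temperature": TemperatureConfig, "attrition": AttritionConfig,
    "questionnaire": QuestionnaireConfig, "analysis": AnalysisOptions,
}


def config_from_dict(data: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a nested plain dict (YAML layer)."""
    kwargs = {}
    for key, value in data.items():
        if key == "seed":
            kwargs["seed"] = int(value)
        elif key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            kwargs[key] = cls(**value)
        else:
            raise ValueError(f"unknown config section {key!r}")
    return SyntheticConfig(**kwargs)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_AGE_BETA = (1.2, 2.8)  # right-skewed on [6, 84], median ~26 years


def generate_cohort(config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Participant roster: per cycle, exact arm counts, ~50/50 sexes,
    right-skewed ages on [6, 84]."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    d = config.design
    rows = []
    pid = 0
    for cycle in range(1, d.n_cycles + 1):
        start = BASE_START + pd.Timedelta(days=(cycle - 1) * d.cycle_length_days)
        arms = np.array([1] * d.arm1_per_cycle + [2] * d.arm2_per_cycle)
        rng.shuffle(arms)
        ages = np.clip(np.round(6 + 78 * rng.beta(*_AGE_BETA, size=d.participants_per_cycle)),
                       6, 84).astype(int)
        sexes = np.where(rng.random(d.participants_per_cycle) < 0.5, "female", "male")
        for i in range(d.participants_per_cycle):
            pid += 1
            rows.append({
                "participant_id": f"P{pid:03d}",
                "sex": sexes[i],
                "age_years": int(ages[i]),
                "arm": int(arms[i]),
                "cycle": cycle,
                "enrollment_start": start,
                "enrollment_end": start + pd.Timedelta(days=d.cycle_length_days - 1),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# wear sessions
# ---------------------------------------------------------------------------


def simulate_wear_sessions(participant, config: SyntheticConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Latent wear sessions (truth for recovery tests).

    Wrist: on each wear day, a stationary alternating renewal process of
    exponential bouts/gaps over the whole 24-h day.  Patch (arm 2 only):
    one session per night from sampled bed/wake times, absent with
    ``detach_prob_per_night``; with ``record_when_detached`` the detached
    nights appear under scope ``patch_detached`` (device off the body but
    still logging ambient temperature).
    """
    w, s = config.wear, config.sleep
    start = pd.Timestamp(participant.enrollment_start)
    n_days = (pd.Timestamp(participant.enrollment_end) - start).days + 1
    window_end_min = n_days * _DAY_MIN
    pi = (w.mean_wear_bout_min / (w.mean_wear_bout_min + w.mean_gap_min)
          if (w.mean_wear_bout_min + w.mean_gap_min) > 0 else 0.0)
    rows: list[tuple[str, float, float]] = []

    for day in range(n_days):
        if w.daily_wear_prob <= 0 or rng.random() >= w.daily_wear_prob:
            continue
        if w.mean_wear_bout_min <= 0:
            continue
        day0 = day * _DAY_MIN
        if w.mean_gap_min <= 0:
            rows.append(("wrist", day0, day0 + _DAY_MIN))
            continue
        t = 0.0
        wearing = rng.random() < pi
        while t < _DAY_MIN:
            if wearing:
                bout = rng.exponential(w.mean_wear_bout_min)
                rows.append(("wrist", day0 + t, day0 + min(t + bout, _DAY_MIN)))
                t += bout
            else:
                t += rng.exponential(w.mean_gap_min)
            wearing = not wearing

    if participant.arm == 2:
        t = config.temperature
        bed_mu, wake_mu = _parse_clock(s.bedtime_mean), _parse_clock(s.wake_mean)
        for night in range(n_days):
            bed = night * _DAY_MIN + bed_mu + rng.normal(0.0, s.bedtime_sd_min)
            wake = (night + 1) * _DAY_MIN + wake_mu + rng.normal(0.0, s.wake_sd_min)
            detached = rng.random() < t.detach_prob_per_night
            if detached and not t.record_when_detached:
                continue
            scope = "patch_detached" if detached else "patch"
            bed = min(max(bed, night * _DAY_MIN), window_end_min)
            wake = min(wake, window_end_min)
            if wake > bed:
                rows.append((scope, bed, wake))

    out = pd.DataFrame(rows, columns=["scope", "start_min", "end_min"])
    out.insert(0, "participant_id", participant.participant_id)
    out["start"] = start + pd.to_timedelta(np.floor(out["start_min"] * 60), unit="s")
    out["end"] = start + pd.to_timedelta(np.floor(out["end_min"] * 60), unit="s")
    return out[["participant_id", "scope", "start", "end"]]


def _sessions_minutes(sessions: pd.DataFrame, scopes, start: pd.Timestamp
                      ) -> tuple[np.ndarray, np.ndarray]:
    sel = sessions[sessions["scope"].isin(scopes)]
    s = (pd.to_datetime(sel["start"]) - start).dt.total_seconds().to_numpy() / 60.0
    e = (pd.to_datetime(sel["end"]) - start).dt.total_seconds().to_numpy() / 60.0
    order = np.argsort(s)
    return s[order], e[order]


def _steps_rate_table(a: ActivityConfig) -> np.ndarray:
    """steps/hour by clock hour."""
    rate = np.full(24, a.night_steps_per_hour)
    day = np.arange(a.day_start_hour, a.day_end_hour)
    rate[day] = a.base_steps_per_hour
    dip = np.arange(a.dip_start_hour, a.dip_end_hour)
    rate[dip] = a.base_steps_per_hour * a.midday_dip_factor
    return rate


# ---------------------------------------------------------------------------
# streams
# ---------------------------------------------------------------------------


def simulate_stream(participant, sessions: pd.DataFrame, spec: StreamSpec,
                    config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Measurement records for one stream of one participant.

    accelerometer: per-epoch Poisson step counts at 30-min epochs anchored
    to each wrist session, emitted only when the count is positive.
    heart_rate: one record per 10-min clock slot inside a wrist session,
    emitted with ``sample_success_prob``.
    temperature: one record per minute inside patch sessions (body-
    distributed values; ambient-distributed for ``patch_detached``).
    """
    start = pd.Timestamp(participant.enrollment_start)
    if spec.stream == "accelerometer":
        s, e = _sessions_minutes(sessions, ("wrist",), start)
        if s.size == 0:
            return _records_frame(participant, spec.stream, np.array([]), np.array([]), start)
        a = config.activity
        epoch = a.epoch_min
        n_ep = np.ceil((e - s) / epoch).astype(int)
        total = int(n_ep.sum())
        if total == 0:
            return _records_frame(participant, spec.stream, np.array([]), np.array([]), start)
        sess_idx = np.repeat(np.arange(len(s)), n_ep)
        within = np.arange(total) - np.repeat(np.cumsum(n_ep) - n_ep, n_ep)
        t = s[sess_idx] + within * epoch
        length = np.minimum(epoch, e[sess_idx] - t)
        hour = ((t // 60) % 24).astype(int)
        lam = _steps_rate_table(a)[hour] * length / 60.0
        counts = rng.poisson(lam)
        keep = counts > 0
        return _records_frame(participant, spec.stream, t[keep],
                              counts[keep].astype(float), start)

    if spec.stream == "heart_rate":
        s, e = _sessions_minutes(sessions, ("wrist",), start)
        h = config.heart
        n_days = (pd.Timestamp(participant.enrollment_end) - start).days + 1
        cadence = spec.cadence_min or 10.0
        slots = np.arange(0.0, n_days * _DAY_MIN, cadence)
        if s.size:
            idx = np.searchsorted(s, slots, side="right") - 1
            worn = (idx >= 0) & (slots < e[np.maximum(idx, 0)])
        else:
            worn = np.zeros(slots.size, dtype=bool)
        emitted = worn & (rng.random(slots.size) < h.sample_success_prob)
        t = slots[emitted]
        hour_frac = (t / 60.0) % 24
        hour = hour_frac.astype(int)
        step_rate = _steps_rate_table(config.activity)[hour] / 60.0  # steps/min
        value = (h.rest_bpm_mean
                 + h.activity_coupling * step_rate
                 + h.diurnal_amp_bpm * np.cos(2 * np.pi * (hour_frac - h.diurnal_peak_hour) / 24)
                 + rng.normal(0.0, h.rest_bpm_sd, size=t.size))
        return _records_frame(participant, spec.stream, t, np.round(value, 1), start)

    if spec.stream == "temperature":
        tconf = config.temperature
        ts, vals = [], []
        sel = sessions[sessions["scope"].isin(("patch", "patch_detached"))]
        for row in sel.itertuples(index=False):
            s_min = (pd.Timestamp(row.start) - start).total_seconds() / 60.0
            e_min = (pd.Timestamp(row.end) - start).total_seconds() / 60.0
            t = np.arange(np.ceil(s_min), e_min, spec.cadence_min or 1.0)
            if row.scope == "patch_detached":
                v = rng.normal(tconf.ambient_mean_c, tconf.ambient_sd_c, size=t.size)
            else:
                v = rng.normal(tconf.body_mean_c, tconf.body_sd_c, size=t.size)
            ts.append(t)
            vals.append(np.round(v, 2))
        t = np.concatenate(ts) if ts else np.array([])
        v = np.concatenate(vals) if vals else np.array([])
        return _records_frame(participant, spec.stream, t, v, start)

    raise ValueError(f"unknown stream {spec.stream!r}")


def _records_frame(participant, stream: str, t_min: np.ndarray,
                   values: np.ndarray, start: pd.Timestamp) -> pd.DataFrame:
    ts = start + pd.to_timedelta(np.floor(np.asarray(t_min, dtype=float) * 60.0), unit="s")
    return pd.DataFrame({
        "participant_id": participant.participant_id,
        "stream": stream,
        "timestamp": ts,
        "value": np.asarray(values, dtype=float),
    })


# ---------------------------------------------------------------------------
# attrition
# ---------------------------------------------------------------------------


def visit_schedule(design: StudyDesign, cycle_start: pd.Timestamp) -> list[pd.Timestamp]:
    """Sync points: midnight after each visit day (every 4th day)."""
    return [cycle_start + pd.Timedelta(days=d) for d in design.visit_days()]


def apply_sync_loss(records: pd.DataFrame, roster: pd.DataFrame,
                    config: SyntheticConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply sync-buffer loss and device failure.

    At each visit the buffer since the previous visit is dropped whole
    with ``sync_failure_prob_per_visit`` (per device); the block after
    the final visit is read out at device return and always survives.  A
    geometric failure day per device censors all its later records.
    Draws are functions of per-(participant, device, block) uniforms, so
    coupling seeds makes record counts monotone in the failure knobs.

    Returns (surviving records, device-failure truth table).
    """
    att = config.attrition
    p_fail, hazard = att.sync_failure_prob_per_visit, att.device_failure_hazard_per_day
    design = config.design
    keep_mask = np.ones(len(records), dtype=bool)
    failures = []
    recs_by_pid = records.groupby("participant_id", sort=False).indices

    for row in roster.sort_values("participant_id").itertuples(index=False):
        start = pd.Timestamp(row.enrollment_start)
        visits = visit_schedule(design, start)
        boundaries = np.array([(v - start).total_seconds() for v in visits])
        for device in ("wristband", "patch"):
            u_blocks = rng.random(len(boundaries))
            u_fail = rng.random()
            if device == "patch" and row.arm != 2:
                continue
            if hazard > 0:
                fail_day = int(np.ceil(np.log(u_fail) / np.log1p(-hazard)))
            else:
                fail_day = None
            failures.append({"participant_id": row.participant_id, "device": device,
                             "failure_day": fail_day if fail_day is not None else -1})
            idx = recs_by_pid.get(row.participant_id)
            if idx is None or len(idx) == 0:
                continue
            sub = records.iloc[idx]
            on_device = sub["stream"].map(DEVICE_OF_STREAM).to_numpy() == device
            rel_s = (pd.to_datetime(sub["timestamp"]) - start).dt.total_seconds().to_numpy()
            drop = np.zeros(len(sub), dtype=bool)
            block = np.searchsorted(boundaries, rel_s, side="left")
            dropped_blocks = np.flatnonzero(u_blocks < p_fail)
            drop |= np.isin(block, dropped_blocks)
            if fail_day is not None:
                drop |= rel_s >= (fail_day - 1) * 86400.0
            keep_mask[idx[on_device & drop]] = False

    out = records[keep_mask].reset_index(drop=True)
    return out, pd.DataFrame(failures)


# ---------------------------------------------------------------------------
# questionnaires
# ---------------------------------------------------------------------------


def _likert_probs(agreement: float, polarity: str) -> np.ndarray:
    """Categorical response distribution (1..5) with the given positive
    agreement after polarity reversal."""
    a, d = agreement, 1.0 - agreement
    probs = np.array([0.15 * d, 0.25 * d, 0.60 * d, 0.30 * a, 0.70 * a])
    if polarity == "negative":
        probs = probs[::-1]
    return probs / probs.sum()


def simulate_questionnaires(roster: pd.DataFrame, config: SyntheticConfig,
                            rng: np.random.Generator
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Likert + multiple-choice responses, one questionnaire per visit.

    Every participant answers all 17 catalog items at each of the 5
    visits (technical-feasibility items are answered by the field worker
    during that participant's visit).  MC answers follow configurable
    multinomials loosely echoing the study's response shares.
    """
    from .acceptability_analysis import default_likert_catalog, default_mc_catalog

    catalog = default_likert_catalog()
    q = config.questionnaire
    if catalog["polarity"].isna().any():
        raise ValueError("item catalog is missing polarity flags")
    lik_rows, mc_rows = [], []
    mc_catalog = default_mc_catalog()
    for prow in roster.sort_values("participant_id").itertuples(index=False):
        for visit in range(1, q.visits + 1):
            for item in catalog.itertuples(index=False):
                agreement = (q.agreement_prob if q.agreement_prob is not None
                             else item.default_agreement)
                r = int(rng.choice(5, p=_likert_probs(agreement, item.polarity)) + 1)
                lik_rows.append((prow.participant_id, visit, item.item_id, r))
            for mq in mc_catalog:
                if mq.multi_select:
                    picks = [o for o, p in zip(mq.options, mq.default_probs)
                             if rng.random() < p]
                    if not picks:
                        picks = [mq.options[int(np.argmax(mq.default_probs))]]
                else:
                    picks = [mq.options[int(rng.choice(len(mq.options),
                                                       p=np.asarray(mq.default_probs)))]]
                for opt in picks:
                    mc_rows.append((prow.participant_id, visit, mq.question_id, opt, ""))
    likert = pd.DataFrame(lik_rows, columns=["participant_id", "visit_index",
                                             "item_id", "response"])
    mc = pd.DataFrame(mc_rows, columns=["participant_id", "visit_index",
                                        "question_id", "option", "free_text"])
    return likert, mc


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_study(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Full deterministic simulation: roster, measurements, truth tables,
    questionnaire responses."""
    ss = np.random.SeedSequence(config.seed)
    n_total = config.design.n_cycles * config.design.participants_per_cycle
    children = ss.spawn(n_total + 3)
    rng_cohort = np.random.default_rng(children[0])
    roster = generate_cohort(config, rng_cohort)
    specs = default_stream_specs()

    all_sessions, all_records = [], []
    for i, prow in enumerate(roster.itertuples(index=False)):
        rng_p = np.random.default_rng(children[1 + i])
        sessions = simulate_wear_sessions(prow, config, rng_p)
        all_sessions.append(sessions)
        for stream in STREAM_ORDER:
            if stream == "temperature" and prow.arm != 2:
                continue
            all_records.append(simulate_stream(prow, sessions, specs[stream],
                                               config, rng_p))
    sessions = pd.concat(all_sessions, ignore_index=True)
    records = pd.concat(all_records, ignore_index=True)
    records = records.sort_values(["participant_id", "stream", "timestamp"],
                                  kind="mergesort").reset_index(drop=True)

    rng_sync = np.random.default_rng(children[n_total + 1])
    records, failures = apply_sync_loss(records, roster, config, rng_sync)

    rng_q = np.random.default_rng(children[n_total + 2])
    likert, mc = simulate_questionnaires(roster, config, rng_q)

    return {"roster": roster, "measurements": records, "wear_sessions": sessions,
            "device_failures": failures, "likert": likert, "mc": mc}


STREAM_ORDER = ("accelerometer", "heart_rate", "temperature")


# ---------------------------------------------------------------------------
# analytic expectations
# ---------------------------------------------------------------------------


def _f_within(q: float, cadence: float, tol: float) -> float:
    """Stationary covered fraction inside a wear session.

    Points sit on a cadence grid and are emitted independently with
    probability ``q``; each emitted point covers forward
    ``min(tol, gap to the next emitted point)``, so the covered fraction
    is ``(q / cadence) * E[min(tol, cadence * K)]`` with K geometric(q).
    """
    if q <= 0:
        return 0.0
    kmax = int(np.ceil(tol / cadence))
    e = 0.0
    for k in range(1, kmax):
        e += q * (1 - q) ** (k - 1) * cadence * k
    e += (1 - q) ** (kmax - 1) * tol
    return min(1.0, (q / cadence) * e)


def _e_min_tail(tol_eff: float, mean_gap: float) -> float:
    """E[min(tol_eff, G)] for exponential G."""
    if mean_gap <= 0:
        return 0.0
    return mean_gap * (1.0 - np.exp(-tol_eff / mean_gap))


def _retention_per_day(config: SyntheticConfig) -> np.ndarray:
    """P(record on day d survives sync loss and device failure), d=1..n."""
    d = config.design
    n = d.cycle_length_days
    att = config.attrition
    visit_days = d.visit_days()
    last_visit = max(visit_days) if visit_days else 0
    r = np.ones(n)
    for day in range(1, n + 1):
        sync = (1.0 - att.sync_failure_prob_per_visit) if day <= last_visit else 1.0
        alive = (1.0 - att.device_failure_hazard_per_day) ** day
        r[day - 1] = sync * alive
    return r


def _e_clamped_ratio(mu: float, sd: float, denom: float) -> float:
    """E[min(1, X/denom)] for X ~ Normal(mu, sd), X effectively >= 0."""
    if sd <= 0:
        return min(1.0, max(0.0, mu / denom))
    z = (mu - denom) / sd
    # E[(X - denom)+] = sd * phi(z) + (mu - denom) * Phi(z)
    excess = sd * stats.norm.pdf(z) + (mu - denom) * stats.norm.cdf(z)
    return max(0.0, min(1.0, (mu - excess) / denom))


def expected_coverage(config: SyntheticConfig, spec: StreamSpec) -> float:
    """Analytic expected pipeline coverage for one stream.

    Structure: wear fraction of the denominator x within-session covered
    fraction, plus expected tolerance tails at session ends, times the
    per-day sync/device retention, truncated to [0, 1].  For temperature
    the per-day expectation enumerates survival of the evening and
    morning portions of the two adjacent nights and applies a normal
    clamping correction against the sleep reference.
    """
    w, a, h = config.wear, config.activity, config.heart
    design = config.design
    n_days = design.cycle_length_days
    retention = _retention_per_day(config)
    B, G = w.mean_wear_bout_min, w.mean_gap_min
    pi = B / (B + G) if (B + G) > 0 and B > 0 else 0.0
    if w.mean_gap_min <= 0 and B > 0:
        pi = 1.0
    tol = spec.tolerance_min

    if spec.stream in ("accelerometer", "heart_rate"):
        if spec.stream == "accelerometer":
            cadence = a.epoch_min
            rate = _steps_rate_table(a)
            q_by_hour = 1.0 - np.exp(-rate * cadence / 60.0)
            in_session = 60.0 * pi * sum(_f_within(q, cadence, tol) for q in q_by_hour)
            # session-end tolerance tails: ends during active hours leave a
            # tail min(tol - grid offset, gap); the end-of-activity boundary
            # (rate drop at day_end_hour) leaves ~ tol - cadence/2 while worn
            if G > 0 and B > 0:
                day_minutes = (a.day_end_hour - a.day_start_hour) * 60.0
                n_day_ends = pi * day_minutes / B
                offs = np.linspace(0.0, cadence, 33)
                e_tail = np.trapezoid(
                    [_e_min_tail(max(tol - o, 0.0), G) for o in offs], offs) / cadence
                tails = n_day_ends * e_tail + pi * max(tol - cadence / 2.0, 0.0)
            else:
                tails = pi * max(tol - cadence / 2.0, 0.0)
            per_day = in_session + tails
        else:
            cadence = spec.cadence_min or 10.0
            p = h.sample_success_prob
            per_day = pi * _DAY_MIN * _f_within(p, cadence, tol)
        per_day = min(per_day, _DAY_MIN) * w.daily_wear_prob
        cov = per_day * retention / spec.denominator_min
        return float(np.clip(cov, 0.0, 1.0).mean())

    if spec.stream == "temperature":
        t, s = config.temperature, config.sleep
        p_wear = 1.0 - t.detach_prob_per_night
        bed, wake = _parse_clock(s.bedtime_mean), _parse_clock(s.wake_mean)
        tail = max(spec.tolerance_min - (spec.cadence_min or 1.0) / 2.0, 0.0)
        eve_mu, eve_sd = _DAY_MIN - bed, s.bedtime_sd_min
        morn_mu, morn_sd = wake + tail, s.wake_sd_min
        den = spec.denominator_min
        covs = np.empty(n_days)
        for d in range(1, n_days + 1):
            s_eve = p_wear * retention[d - 1]
            s_morn = p_wear * retention[min(d - 2, n_days - 1)] if d >= 2 else 0.0
            both = s_eve * s_morn
            only_e = s_eve * (1 - s_morn)
            only_m = s_morn * (1 - s_eve)
            covs[d - 1] = (
                both * _e_clamped_ratio(eve_mu + morn_mu,
                                        np.hypot(eve_sd, morn_sd), den)
                + only_e * _e_clamped_ratio(eve_mu, eve_sd, den)
                + only_m * _e_clamped_ratio(morn_mu, morn_sd, den))
        return float(np.clip(covs, 0.0, 1.0).mean())

    raise ValueError(f"unknown stream {spec.stream!r}")


def expected_daily_steps(config: SyntheticConfig, include_attrition: bool = False,
                         per_wear_day: bool = True) -> float:
    """Analytic mean step count per day with accelerometer data.

    Conditional on a wear day (the device reports nothing on non-wear
    days); optionally deflated by sync/device retention.
    """
    a = config.activity
    w = config.wear
    pi = (w.mean_wear_bout_min / (w.mean_wear_bout_min + w.mean_gap_min)
          if (w.mean_wear_bout_min + w.mean_gap_min) > 0 else 0.0)
    if w.mean_gap_min <= 0 and w.mean_wear_bout_min > 0:
        pi = 1.0
    steps = pi * float(_steps_rate_table(a).sum())
    if not per_wear_day:
        steps *= w.daily_wear_prob
    if include_attrition:
        steps *= float(_retention_per_day(config).mean())
    return steps
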