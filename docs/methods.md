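# Methods

## The coverage model

A consumer wearable's output is already aggregated by the vendor, and the
device does not distinguish inactivity from non-wear: both produce gaps.
Coverage therefore works on the output stream alone. Each data point
covers a forward tolerance epoch τ — the longest gap after a point still
regarded as covered — and the covered time of a window is the sum over
points of `min(τ, gap to next point or window end)`. Defaults follow the
streams' output cadences: 60 min for accelerometry (the conventional
maximal sedentary bout in actigraphy), 15 min for heart rate sampled
nominally every 10 min, 5 min for a thermometer emitting one value per
minute while attached.

Two formulations of this statistic circulate: summing the *excess* of
each gap over τ and subtracting from the reference duration, or summing
covered time directly. They coincide when the reference is the whole
window, but the excess form can go negative when the reference is a
reduced sleep window (a patch worn 9 h against an 8-h reference). We
compute covered time and clamp `coverage = min(1, covered/denominator)`,
which is well-defined for any denominator and equals the excess form on
full days. Two further conventions are deliberate and documented rather
than implied: the interval before a window's first point is uncovered
(points cover forward only), and participant-level coverage pools minutes
(Σ covered / Σ denominator over enrolled days) rather than averaging
daily ratios, which keeps clamped days from inflating the mean.

Covered intervals are split at local midnight so per-day covered minutes
sum exactly to the undivided value; all timestamps are naive local time
(single site, no DST) and a day is a calendar day of the enrollment
window. The implementation is exact in integer seconds; an independent
1-second grid oracle (`coverage_oracle`) marks second *s* covered iff a
point exists in (s − τ, s] and agrees with the fast path exactly on
whole-second data, which the test suite asserts on a thousand random
fixtures.

The sleep-window denominator defaults to 8 h/day for the night-worn
patch. Sensitivity grids recompute the overall means across tolerance
settings (30/60/90 min for accelerometry, 10/15/30 for heart rate,
5/10/15 for temperature) and sleep references (6–9 h); coverage is
monotone non-decreasing in tolerance, which the suite checks on random
fixtures.

## The synthetic cohort

The generator emulates the deployment that motivated the package: three
consecutive 21-day cycles, 50 participants each (27 wristband-only,
23 wristband + patch), ages drawn right-skewed on [6, 84] with median
≈ 26 (Beta(1.2, 2.8) scaled), sexes balanced, field-worker visits every
4 days (five per cycle).

**Wear.** A participant wears the wristband on a given day with
probability 0.95; within a wear day, wear follows a stationary
alternating renewal process over the full 24-h day with exponential
bouts (mean 300 min) and gaps (mean 60 min), so the stationary wear
probability is π = B/(B+G) at every clock time and the long-run wear
fraction is 0.95 · π ≈ 0.79. The wristband is worn at night as well
(it is the device that tracks sleep); night-time *activity* is still
near zero. The patch is worn per night with probability
1 − detach = 0.1 between sampled bed (~22:30 ± 30 min) and wake
(~07:00 ± 30 min) times. The high nightly detach probability encodes the
dominant field failure mode of adhesive patches (detachment plus
Bluetooth/sync failure); in the motivating deployment three quarters of
patch wearers ended below 1% completeness.

**Streams.** Accelerometry emits Poisson step counts per 30-min epoch
anchored at each session start, only when the count is positive, so
inactivity and non-wear are indistinguishable in the output — as with
the real device; the latent sessions go to a separate truth table used
only by tests. The hourly step rate is 800 steps/h between 07:00 and
22:00, multiplied by a midday dip factor 0.6 between 12:00 and 18:00
(the afternoon heat lull), and ~0 at night; the defaults give ≈ 8×10³
steps per reporting day. Heart rate emits one record per 10-min clock
slot inside a wear session with success probability 0.05 — PPG reads
fail under loose bands, motion and perspiration, and sparse success is
the realistic regime — with value = 73 bpm + 0.3 · (steps/min) + a 4-bpm
diurnal cosine (peak 13:00) + N(0, 8) noise. Temperature emits one
record per minute while the patch is attached, N(35.5, 0.5) °C; with
`record_when_detached` the detached nights log ambient N(31.0, 0.8) °C
instead, which the plausibility filter flags.

**Attrition.** At each visit the buffer since the previous visit is
dropped whole with probability 0.35 per device (intermittent rural
connectivity makes whole-block loss, not record-level thinning, the
right model); the partial block after the final visit is read out at
device return and always survives. Each device independently fails on a
geometric day with hazard 0.002/day (≈ 4% over a cycle, matching the
handful of lost/damaged devices per deployment). Both draws are
monotone functions of per-(participant, device, block) uniforms, so
coupled seeds make record counts monotone in the failure knobs.

**What the generator does not model:** skin-tone-dependent PPG error,
ambient-temperature physics, vendor sleep staging, GPS, or any
calibration to the (confidential) field data. Passing recovery tests
shows the pipeline measures what the generator injects — not that the
generator reproduces the field distributions beyond their qualitative
ordering (activity coverage ≫ heart-rate ≈ temperature coverage).

## Analytic expected coverage

`expected_coverage` computes, independently of the simulation code path,
the expectation the pipeline should recover:

* Within a session, points on a cadence-c grid emitted with probability
  q cover a stationary fraction f(q) = (q/c) · E[min(τ, cK)], K
  geometric(q): the sparse limit (q→0) gives rate·τ, the dense limit 1.
* A wear day contributes π · Σ_h 60 · f(q_h) plus session-end tolerance
  tails (E[min(τ − U, G)], U uniform grid offset, G the exponential gap)
  at rate π/B per minute of active hours, plus the end-of-activity
  boundary tail.
* Per-day sync/device retention multiplies in exactly:
  (1 − p_sync) for days up to the last visit, 1 after, times
  (1 − h)^day device survival.
* For temperature the per-day expectation enumerates survival of the
  evening portion (night d) and morning portion (night d−1) and applies
  a normal clamping correction E[min(1, X/480)] via the truncated-normal
  mean, since a full night (~8.5 h) saturates the 8-h reference.

On the default cohort (150 × 21 days) ten-seed simulated means agree
with these expectations within ±0.005 per stream; the acceptance suite
asserts ±0.03.

## Physiology and acceptability conventions

Plausibility keep-ranges: temperature 34–41 °C (34–37 labelled normal,
(37, 41] feverish — possibly febrile readings are kept), heart rate
25–220 bpm (wide enough to retain genuine extremes while cutting sensor
nonsense), step epochs ≥ 0. Filtered-out records go to a flagged table;
kept + flagged always partition the input. Distance (0.7 m/step) and
energy (778 kcal basal + 0.064 kcal/step) are transparent linear
stand-ins for undisclosed vendor algorithms — they reproduce the
computation pattern, not vendor magnitudes. Sleep hours come from
night-attributed thermometer minute counts (the patch is worn only
during sleep); records before noon belong to that wake date. Quantiles
use linear interpolation between order statistics; hour bins are
closed-open [h, h+1) local time.

Likert agreement counts top-two-box responses after reverse-coding
negative items (r → 6 − r, an involution); agreement pools responses
across visits by default, with a per-participant-mean alternative behind
a flag, since either pooling is defensible. The default 17-item catalog
carries the documented category/polarity/respondent structure with
placeholder wordings (the published wordings live in supplementary
material). Multiple-choice percentages are always emitted with their
explicit denominator under a stated policy (respondents / participants /
questionnaires); display rounding is half-up to whole percent, internal
values stay unrounded.

## Problem sizes and numerical choices

The acceptance script and the heavier tests run the full default cohort
(150 participants × 21 days) for ten seeds — about 1.8 M records in
total, a couple of minutes end to end — which is the scale at which
binomial standard errors make the ±0.03 coverage and ±2 pp agreement
bands meaningful. Unit tests use a one-cycle, 10-participant design.
Tolerances passed in minutes are snapped to whole seconds when within
1e-6 to keep strict `<`/`≤` boundary comparisons exact; duplicate
records on (participant, stream, timestamp) are resolved by full-row
ordering so validation is idempotent and order-invariant; sample sizes
round up (ceiling) after the finite-population correction, the
conservative convention.

## Known limitations

Coverage for the wristband's derived sleep stream is intentionally not
computed (its completeness is what is under study; activity coverage is
its proxy). The generator's defaults are plausible field knobs, not
estimates fitted to data. Expected-coverage formulas neglect
session-tail overlap across adjacent sessions and day-boundary spill,
both of order a few minutes per day — well inside the stated bands — and
assume the stationary-start renewal construction the simulator uses.
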