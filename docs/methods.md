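# Methods

## The question this package operationalizes

Trunk-mounted IMUs are widely used to characterize running gait, and a
recurring design is to compare a runner's "non-fatigued" (NF) and
"fatigued" (FT) states within a single treadmill run. That design is only
interpretable if fatigue-related changes in the derived features are
*reliable day-to-day*: the same runner, on another day at the same relative
intensity, should show the same feature values in the same fatigue state.
`comgait` implements that reliability analysis end-to-end — signal
simulation, gait segmentation, feature extraction, and the fatigue-state ×
trial ANOVA / ICC(2,k) statistical layer — on a repeated-measures design of
four trials per runner: two at the speed associated with maximal lactate
steady state (MLSS1, MLSS2), one 5% faster (F), one 5% slower (S).

Raw recordings from such protocols are rarely deposited, so the package
ships a synthetic-signal generator as a first-class, tested component. All
empirical statements the test-suite and acceptance script make are about
the pipeline's behavior on that generator.

## The synthetic running signal

Each trial is a tri-axial acceleration series in g, axes VT (vertical, +
up, gravity included), ML (medio-lateral), AP (antero-posterior), at a
configurable rate (default 1125 Hz, range clipped at ±16 g, matching a
research-grade trunk IMU). A trial is: 2 s of quiet standing, a 5-min
warmup at 1.92 m/s (lower cadence and amplitudes), then the main run at
the trial's target speed until termination (nominally drawn per trial
label; capped at 45 min).

Per step of duration `T = 60/cadence` (with Gaussian timing jitter), the
waveform is

- `VT(τ) = 1 + a_vt·sin(2πτ/T) + I·exp(−τ/τ_i)`
- `ML(τ) = ±( a_ml·sin(πτ/T) + 0.15·I·exp(−τ/τ_i) )` (sign alternates per foot)
- `AP(τ) = a_ap·sin(2πτ/T) − 0.30·I·exp(−τ/τ_i)`

plus white sensor/tissue noise per axis. The exponential impact transient
`I·exp(−τ/τ_i)` (default I = 2.5 g, τ_i = 22 ms) is the initial-contact
(IC) landmark: its maximum falls on the IC sample itself, and it
dominates the mid-step oscillation crest (≈ 1 + a_vt) by a wide margin,
which is what makes IC detection well-posed. The rationale for this family
is minimality: one controllable per-axis amplitude, one regularity channel
(noise + timing jitter), and one detectable IC landmark — nothing more is
needed to exercise every downstream stage. A small random mounting tilt
(default sd 3° about the ML and AP axes, no yaw) is applied to the whole
recording so the attitude-correction stage has real work to do.

### Variance structure

Every waveform parameter carries a hierarchy of Gaussian effects:
subject-level traits drawn once per runner and shared across their four
trials (`between_subject_sd`), independent trial-level perturbations
(`between_trial_sd`, the quantity that reliability is *about*),
and stride-to-stride within-trial variation (`within_trial_sd`). Defaults
put trial-level spreads at roughly a third of subject-level spreads, with
the ML axis relatively noisier between trials — the configuration a
reliability study of trained runners would call realistic: it yields
good-to-excellent ICCs with the ML axis weakest, without any parameter
being fit to published numbers. Trial speed is recorded metadata only; by
default it does not alter the waveform (a ±5% speed change is treated as
biomechanically neutral), so the four trials are exchangeable up to their
random effects and any "trial" main effect in the analysis is a false
positive by construction.

### Fatigue

`fatigue_effects` is a dict of additive shifts on waveform parameters.
Defaults raise all amplitudes (most strongly the impact and ML terms),
raise VT noise (less regular vertical signal → sample entropy up) and
lower ML noise (more constrained ML control → sample entropy down) — the
typical fatigued-running signature. The shift ramps linearly from the
*end of the NF window* to the *start of the FT window* and plateaus
there. This schedule keeps the NF window cleanly unfatigued and the FT
window entirely on the plateau for any termination time; an earlier
variant that ramped from main-speed onset to termination leaked a
duration-dependent fraction of the effect into the NF window and thereby
manufactured fatigue × trial interactions the design does not intend.

RPE (Borg 6–20) is simulated as a saturating, monotone ramp read every
5 min (≈ 11 at the start, ≈ 14–17 at termination depending on trial
label); it exists to exercise the RPE statistics, nothing downstream of
the feature pipeline reads it.

A second, feature-level generator (`simulate_condition_means`) draws
subject × trial × window condition means directly from the measurement
model `y = μ + S_i + T_j + δ·1[FT] + ε`. The statistical layer's
calibration suites (type-I error, power, ICC parameter recovery) sample
from it — the structure being calibrated is identical, and a hundred
signal-level cohorts would add nothing but runtime.

## Preprocessing

- **Attitude correction.** The mean acceleration over a static window
  (default: the standing prelude) estimates gravity; the minimal rotation
  mapping it onto +VT (no yaw component) is applied to the whole trial.
  Windows shorter than 0.5 s, with |a| sd above 0.05 g, or with mean
  magnitude below 0.5 g (free fall / corrupt) are rejected. Norms are
  preserved exactly, so the resultant is rotation-invariant.
- **IC detection.** Local maxima of the corrected resultant above
  median + 2·MAD, with minimum peak separation 0.7 of the expected step
  period (ICs sit a full period apart; mid-step crests sit half a period
  from them, so 0.7 rejects crests while honouring the half-period
  minimum-spacing contract). The simulated transient peaks on the IC
  sample, so no onset refinement is applied; accuracy is validated against
  simulator ground truth (max error < 2 ms on noiseless trials, tolerance
  ±10 ms), not against any published detector.
- **Step/stride segmentation.** Steps are consecutive IC-to-IC intervals;
  lengths (in samples) beyond ±2 population SD of the pre-exclusion mean
  are excluded (SD = 0 ⇒ no exclusions). Feet are unknowable from one CoM
  sensor, so ICs alternate by convention; within each maximal run of
  retained steps, strides pair steps (0,1), (2,3), … — an excluded step
  splits the stream and nothing spans the gap. Note that with Gaussian
  timing jitter the rule removes ≈ 4.6% of steps by construction; that is
  the rule operating as specified, not a defect.
- **Windows.** NF = the first 5 min at the main speed (warmup excluded —
  including the 1.92 m/s warmup would mix speeds within NF); FT = the
  last *complete* 5-min block on the 5-min RPE grid (termination at 38 min
  ⇒ FT = 30–35 min). Windows must not overlap (trial ≥ warmup + 10 min).
  Within each window, steps are re-filtered (mean/SD over that window's
  steps) and non-overlapping consecutive groups of five strides become
  samples; overlap is avoided because overlapping samples would
  pseudo-replicate within-condition means. Each sample carries the RPE
  read at the window's end.

## Features (39 per sample)

Nine statistics — mean, SD (n−1), median, 25th/75th percentile (linear
interpolation), RMS, max, min, sample entropy — on each of VT, ML, AP and
the resultant RES, plus the three RMS ratios RMSR_axis = RMS_axis /
RMS_RES (RES has no ratio with itself, hence 9×4 + 3 = 39). Signals are
never filtered. The ratios satisfy ΣRMSR² = 1 identically.

Sample entropy follows Richman–Moorman: SampEn(m, r·SD) = −ln(A/B) with
Chebyshev distance, self-matches excluded, both counts over the first
N−m templates; m = 2 and r = 0.2 are the dominant convention in the
physiological-entropy literature and are exposed in configuration.
Undefined entropy (no matches at either length) returns NaN — a flagged
sentinel, excluded from condition means with a logged count — never
infinity. A constant segment is perfectly regular: A = B, SampEn = 0.

The entropy input uses a gait-cycle rather than time-sample base: each of
the five strides is linearly resampled to 200 points (configurable) and
concatenated, making the input commensurate across cadences and trials.
The default 1000-point input is below the ≈ 2000 points where SampEn is
fully stabilized; the implementation logs this once and the
`points_per_stride` knob (or `stride_bounds=None` for raw-time entropy)
exists for sensitivity checks. The tension — cycle-normalized density vs
absolute-point stability — is inherent to the gait-cycle approach and is
deliberately surfaced rather than hidden.

## Statistics

All designs are fully within-subject, so both ANOVAs are
repeated-measures: each effect is tested against its own
subject-by-effect interaction mean square. They are computed from
closed-form balanced sums of squares rather than a library call because
the degenerate inputs the contracts require (identical cells, zero
residual variance) need explicit conventions — 0/0 ⇒ (F = 0, p = 1), a
perfectly replicated effect ⇒ (F = ∞, p = 0) — where generic
implementations return NaN; `statsmodels.AnovaRM` serves as the
independent cross-check in tests (agreement to 1e−9 on non-degenerate
data). No sphericity correction is applied: the fatigue factor has two
levels (none needed) and no correction is part of the modeled analysis.
No multiple-testing correction is applied either; instead the
chance-expectation diagnostic n_comparisons × α (78 × 0.05 = 3.9 ≈ 4) is
reported alongside the significance counts.

Reliability is ICC(2,k) — two-way random effects, absolute agreement,
average measures:

    ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

with bins < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent.
Absolute agreement is the right form here because a systematic
between-day shift *is* unreliability for this question; a directional
test confirms that adding a trial-specific constant lowers the ICC.
Missing cells are handled by listwise deletion (logged); fewer than three
complete subjects is an error; a non-positive denominator is flagged
degenerate (NaN) rather than reported as a number. Features with
near-zero between-subject variance (the ML mean is ≈ 0 by symmetry) can
take large negative ICCs at small n; the analysis drivers therefore
report medians alongside means for small cohorts.

The fatigue-effect direction is sign(FT − NF grand means), reported only
when the effect is significant at α = 0.05. The MLSS identification rule
is implemented as stated: steady iff ≥ 30 min completed and blood lactate
rises < 1 mmol/L between minutes 10 and 30.

## Problem sizes and numerical choices

- Acceptance runs use the full 16-runner × 4-trial design at 1125 Hz with
  trial durations ~15–17 min (vs the protocol's ~29–42 min); duration
  scales only the number of five-stride samples per window (~90 here),
  not the structure of any contract, and keeps a single-CPU rerun in
  minutes. The demonstration drivers under `analysis/` use 8 runners at
  125 Hz for the same reason.
- Calibration suites run 100 replicates at the design's n = 16; ICC
  parameter recovery uses n = 500 subjects and averages 10 replicates
  because the ICC(2,k) estimator's sampling SD (~0.024 at n = 500, k = 2)
  exceeds the ±0.05 check on single draws.
- All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning (one stream per subject for traits, one per subject-trial for
  everything else); identical seeds give bit-identical cohorts and
  byte-identical output files (fixed column order and float format).
- Indexing is 0-based half-open throughout; percentiles use linear
  interpolation; the SampEn kernel is numba-accelerated when numba is
  importable, with an equivalent vectorized NumPy fallback (both are
  checked against the brute-force oracle).

## What the generator does and does not emulate

It emulates: the periodic CoM-acceleration geometry with an IC impact
landmark, gravity in VT before correction, mounting tilt, the
subject/trial/stride variance hierarchy, fatigue-state effects with the
literature's typical signs, warmup/termination protocol structure, and
RPE logging. It does not emulate: musculoskeletal dynamics, asymmetric or
pathological gait, soft-tissue resonance, sensor drift or temperature
effects, gyroscope/magnetometer channels, overground or outdoor running,
or speed-dependent waveform changes. Consequently, passing tests
demonstrate that the *pipeline and statistics* behave correctly under the
assumed measurement model — they are not evidence about any real cohort,
and published empirical ICC magnitudes from real cohorts are not
reproduction targets.

## Known limitations

- The IC detector is validated against this generator's ground truth
  only; real trunk accelerometry with weak impact transients (forefoot
  strikers, soft surfaces) would need the threshold factor re-examined.
- Foot laterality is conventional, not physical; left/right-specific
  stride statistics are out of reach of a single CoM sensor here.
- The ±2 SD step filter assumes roughly Gaussian step durations; heavy
  drift within a window would bias the pre-exclusion mean.
- ICC listwise deletion is the only missingness strategy implemented.
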