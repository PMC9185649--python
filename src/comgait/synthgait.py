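"""Synthetic running-trial acceleration signals.

Generates cohorts of treadmill running trials as a center-of-mass (CoM)
mounted tri-axial accelerometer would record them: a periodic stride
waveform with an impact transient at each initial contact (IC), gravity
included in the vertical channel, a small random mounting tilt, and a
hierarchical variance structure (subject traits, trial-level perturbations,
stride-to-stride variation) with configurable fatigue-state effects that
ramp in over the run.

Axis convention is VT/ML/AP (vertical +up, medio-lateral, antero-posterior),
units of g, matching research-grade trunk IMUs. Each trial carries 2 s of
quiet standing before the warmup (time < 0 on the trial clock) so that the
static attitude-correction stage downstream has a genuine job to do.

The module also provides ``simulate_condition_means``, a feature-level
generator that draws subject-condition mean tables directly from the same
variance-component model; the statistical layer's calibration suites
(type-I error, power, ICC recovery) run on it.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

TRIAL_LABELS = ("MLSS1", "MLSS2", "F", "S")

#: fractional speed offset relative to MLSS speed per trial label
SPEED_OFFSETS = {"MLSS1": 0.0, "MLSS2": 0.0, "F": +0.05, "S": -0.05}

#: nominal trial-duration multipliers per label (the faster trial is
#: terminated earlier, the slower one lasts longer, mirroring how time to
#: exhaustion scales around a sustainable-intensity anchor)
DURATION_MULT = {"MLSS1": 1.0, "MLSS2": 0.97, "F": 0.74, "S": 1.08}

#: stride-shape parameters (units of g unless noted)
DEFAULT_STRIDE_PARAMS = {
    "amp_vt": 0.80,      # vertical oscillation amplitude
    "amp_ml": 0.35,      # medio-lateral sway amplitude (sign alternates per foot)
    "amp_ap": 0.45,      # antero-posterior oscillation amplitude
    "impact_amp": 2.50,  # impact-transient peak at IC
    "impact_tau": 0.022,  # impact decay constant, s
    "noise_vt": 0.12,    # broadband sensor+tissue noise sd per axis
    "noise_ml": 0.08,
    "noise_ap": 0.08,
    "jitter_sd": 0.012,  # relative sd of step duration (timing regularity)
}

#: parameters that cannot go negative after random perturbation; impact_tau
#: is a divisor and additionally needs a strictly positive floor
_SCALE_PARAMS = ("amp_vt", "amp_ml", "amp_ap", "impact_amp", "impact_tau",
                 "noise_vt", "noise_ml", "noise_ap", "jitter_sd")
_TAU_FLOOR = 1e-4


def _param_floor(name: str) -> float:
    return _TAU_FLOOR if name == "impact_tau" else 0.0

DEFAULT_BETWEEN_SUBJECT_SD = {
    "amp_vt": 0.15, "amp_ml": 0.08, "amp_ap": 0.09, "impact_amp": 0.40,
    "noise_vt": 0.020, "noise_ml": 0.015, "noise_ap": 0.015,
    "jitter_sd": 0.003, "cadence": 6.0,
}

DEFAULT_BETWEEN_TRIAL_SD = {
    "amp_vt": 0.050, "amp_ml": 0.045, "amp_ap": 0.032, "impact_amp": 0.13,
    "noise_vt": 0.007, "noise_ml": 0.006, "noise_ap": 0.005,
    "jitter_sd": 0.001, "cadence": 2.0,
}

#: stride-to-stride relative jitter applied to amplitude parameters
DEFAULT_WITHIN_TRIAL_SD = {
    "amp_vt": 0.04, "amp_ml": 0.06, "amp_ap": 0.04, "impact_amp": 0.06,
}

#: additive shifts reached at the fatigue plateau (last 5 min), expressing
#: the typical fatigued-running signature: larger accelerations on every
#: axis (strongest relative growth on ML), a less regular vertical signal
#: and a more constrained, more regular ML signal
DEFAULT_FATIGUE_EFFECTS = {
    "amp_vt": 0.07, "amp_ml": 0.07, "amp_ap": 0.05, "impact_amp": 0.18,
    "noise_vt": 0.030, "noise_ml": -0.012,
}


class ParameterError(ValueError):
    """A simulator parameter is invalid (non-finite, negative, out of range)."""


@dataclass
class CohortSpec:
    """Design of a synthetic four-trial repeated-measures cohort.

    Defaults mirror the modeled protocol: 16 runners, 1125 Hz sampling,
    two trials at the speed at maximal lactate steady state (MLSS1/MLSS2)
    plus one 5% faster (F) and one 5% slower (S), a 5-min warmup at
    1.92 m/s, trials capped at 45 min, RPE logged every 5 min.
    """

    n_subjects: int = 16
    sampling_rate: float = 1125.0
    trial_labels: tuple = TRIAL_LABELS
    speed_mlss_mean: float = 3.35          # m/s
    speed_mlss_sd: float = 0.40            # between-subject sd of MLSS speed
    speed_offsets: dict = field(default_factory=lambda: dict(SPEED_OFFSETS))
    cadence_mean: float = 180.0            # steps/min
    trial_duration: float = 38.0           # nominal main-run duration, min
    trial_duration_sd: float = 3.0         # min
    max_duration: float = 45.0             # min, hard cap
    warmup_duration: float = 5.0           # min
    warmup_speed: float = 1.92             # m/s
    standing_duration: float = 2.0         # s of quiet standing before warmup
    mount_tilt_sd_deg: float = 3.0         # sd of sensor mounting tilt angles
    stride_params: dict = field(default_factory=lambda: dict(DEFAULT_STRIDE_PARAMS))
    between_subject_sd: dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD))
    between_trial_sd: dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_TRIAL_SD))
    within_trial_sd: dict = field(default_factory=lambda: dict(DEFAULT_WITHIN_TRIAL_SD))
    fatigue_effects: dict = field(default_factory=lambda: dict(DEFAULT_FATIGUE_EFFECTS))
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.sampling_rate <= 0 or self.cadence_mean <= 0:
            raise ParameterError("sampling_rate and cadence_mean must be > 0")
        for name in ("between_subject_sd", "between_trial_sd", "within_trial_sd"):
            bad = {k: v for k, v in getattr(self, name).items() if v < 0}
            if bad:
                raise ParameterError(f"negative variance components in {name}: {bad}")
        for label in self.trial_labels:
            if label not in self.speed_offsets:
                raise ParameterError(f"no speed offset for trial label {label!r}")
        _check_finite(self.stride_params)
        _check_finite(self.fatigue_effects)

    def speed_for(self, label: str, speed_mlss: float) -> float:
        return speed_mlss * (1.0 + self.speed_offsets[label])

    @property
    def min_duration(self) -> float:
        """Smallest main-run duration (min) with disjoint NF and FT windows."""
        nf_end = self.warmup_duration + 5.0
        return 5.0 * math.ceil(nf_end / 5.0) + 5.0


@dataclass
class RawTrial:
    """One trial's recorded acceleration plus protocol metadata.

    ``time`` starts at ``-standing_duration``; the trial clock (warmup onset)
    is t = 0 and the main speed begins at ``warmup_duration``. ``duration``
    is the trial duration in seconds excluding the standing prelude, so the
    array length is ``round((standing_duration + duration) * sampling_rate)``.
    """

    subject_id: str
    trial_label: str
    sampling_rate: float
    time: np.ndarray            # seconds, trial clock
    accel: np.ndarray           # (n, 3) in g, columns VT, ML, AP (sensor frame)
    speed: float                # m/s, main-run treadmill speed
    duration: float             # s, warmup + main run
    warmup_duration: float      # s
    standing_duration: float    # s
    rpe_log: list               # [(minute, rpe 6-20), ...] on the trial clock
    true_ic_times: np.ndarray | None = None   # s, simulator ground truth
    cadence: float | None = None              # steps/min, ground truth

    def __post_init__(self):
        n = int(round((self.standing_duration + self.duration) * self.sampling_rate))
        if len(self.accel) != n:
            raise ParameterError(
                f"accel length {len(self.accel)} != round((standing+duration)*rate) = {n}")
        if np.max(np.abs(self.accel)) > 16.0:
            raise ParameterError("acceleration exceeds the ±16 g sensor range")
        for _, rpe in self.rpe_log:
            if not (6 <= rpe <= 20):
                raise ParameterError(f"RPE {rpe} outside the Borg 6-20 scale")

    @property
    def main_start(self) -> float:
        return self.warmup_duration

    def rpe_at(self, minute: float) -> int:
        """RPE reading at the 5-min mark closest at or before ``minute``."""
        eligible = [r for m, r in self.rpe_log if m <= minute + 1e-9]
        if not eligible:
            raise ValueError(f"no RPE reading at or before minute {minute}")
        return eligible[-1]


def _check_finite(params: dict) -> None:
    bad = {k: v for k, v in params.items() if not np.isfinite(v)}
    if bad:
        raise ParameterError(f"non-finite parameters: {bad}")


def _step_waveforms(t, ic_times, durations, params_per_step, foot_signs, rng=None):
    """Vectorized per-sample waveform for a sequence of steps.

    ``t`` is the global time grid; each sample is attributed to the step whose
    IC precedes it. Per-step parameter arrays allow stride-to-stride and
    fatigue modulation. Returns an (n, 3) array (VT, ML, AP) without sensor
    noise (the caller adds it).
    """
    idx = np.searchsorted(ic_times, t, side="right") - 1
    idx = np.clip(idx, 0, len(ic_times) - 1)
    tau = t - ic_times[idx]
    T = durations[idx]
    phase = np.clip(tau / T, 0.0, 1.0)
    amp_vt = params_per_step["amp_vt"][idx]
    amp_ml = params_per_step["amp_ml"][idx]
    amp_ap = params_per_step["amp_ap"][idx]
    imp = params_per_step["impact_amp"][idx] * np.exp(-tau / params_per_step["impact_tau"][idx])
    sign = foot_signs[idx]
    vt = 1.0 + amp_vt * np.sin(2 * np.pi * phase) + imp
    ml = sign * (amp_ml * np.sin(np.pi * phase) + 0.15 * imp)
    ap = amp_ap * np.sin(2 * np.pi * phase) - 0.30 * imp
    return np.column_stack([vt, ml, ap])


def simulate_stride_waveform(params: dict, cadence: float, sampling_rate: float,
                             rng: np.random.Generator) -> np.ndarray:
    """One stride (two steps) of noiseless VT/ML/AP acceleration in g.

    The vertical channel carries a dominant positive impact peak at each IC
    on top of a gravity-offset oscillation; stride duration is
    2 x (60/cadence) s up to the timing jitter configured in ``params``.
    """
    if cadence <= 0:
        raise ParameterError("cadence must be > 0")
    if sampling_rate < 100:
        raise ParameterError("sampling_rate must be >= 100 Hz")
    _check_finite(params)
    p = {**DEFAULT_STRIDE_PARAMS, **params}
    step = 60.0 / cadence
    durations = step * (1.0 + p["jitter_sd"] * rng.standard_normal(2))
    ic_times = np.array([0.0, durations[0]])
    n = int(round(durations.sum() * sampling_rate))
    t = np.arange(n) / sampling_rate
    per_step = {k: np.full(2, p[k]) for k in
                ("amp_vt", "amp_ml", "amp_ap", "impact_amp", "impact_tau")}
    out = _step_waveforms(t, ic_times, durations, per_step, np.array([1.0, -1.0]))
    noise_sd = np.array([p["noise_vt"], p["noise_ml"], p["noise_ap"]])
    if np.any(noise_sd > 0):
        out = out + rng.standard_normal(out.shape) * noise_sd
    return out


def _mount_rotation(rng: np.random.Generator, tilt_sd_deg: float) -> Rotation:
    """Small random sensor-mounting tilt about the ML and AP axes (no yaw)."""
    ang_ml, ang_ap = np.deg2rad(tilt_sd_deg) * rng.standard_normal(2)
    return Rotation.from_euler("yz", [ang_ml, ang_ap])


def _rpe_schedule(duration_min: float, rng: np.random.Generator,
                  rpe_start: float, rpe_end: float) -> list:
    """Saturating RPE ramp read every 5 min plus at termination; monotone."""
    marks = list(np.arange(5.0, duration_min + 1e-9, 5.0))
    if not marks or marks[-1] < duration_min - 1e-9:
        marks.append(duration_min)
    tau = max(duration_min / 1.8, 1.0)
    vals = []
    for m in marks:
        frac = (1 - math.exp(-m / tau)) / (1 - math.exp(-duration_min / tau))
        v = rpe_start + (rpe_end - rpe_start) * frac + 0.4 * rng.standard_normal()
        vals.append(v)
    vals = np.maximum.accumulate(np.round(vals)).clip(6, 20).astype(int)
    return list(zip([float(m) for m in marks], [int(v) for v in vals]))


def simulate_trial(spec: CohortSpec, subject_effects: dict, trial_label: str,
                   rng: np.random.Generator) -> RawTrial:
    """Simulate one trial: standing, warmup, then the main run with a
    fatigue ramp that starts after the NF window and plateaus before the
    FT window, so the windowed analysis sees a clean unfatigued/fatigued
    contrast.
    """
    if trial_label not in spec.trial_labels:
        raise ParameterError(f"unknown trial label {trial_label!r}")

    # --- trial-level randomness -------------------------------------------
    trial_eff = {k: sd * rng.standard_normal() for k, sd in spec.between_trial_sd.items()}
    base = dict(spec.stride_params)
    cadence = spec.cadence_mean + subject_effects.get("cadence", 0.0) + trial_eff.pop("cadence", 0.0)
    for k in base:
        base[k] = base[k] + subject_effects.get(k, 0.0) + trial_eff.get(k, 0.0)
        if k in _SCALE_PARAMS:
            base[k] = max(base[k], _param_floor(k))
    _check_finite(base)
    if cadence <= 0:
        raise ParameterError("cadence must be > 0 after random effects")

    dur_min = spec.trial_duration * DURATION_MULT.get(trial_label, 1.0)
    dur_min += spec.trial_duration_sd * rng.standard_normal()
    dur_min = float(np.clip(dur_min, spec.min_duration, spec.max_duration))
    if dur_min < spec.warmup_duration + 10.0:
        raise ParameterError(
            f"trial duration {dur_min:.1f} min < warmup + 10 min: "
            "the NF and FT windows would overlap")
    duration_s = dur_min * 60.0
    warmup_s = spec.warmup_duration * 60.0
    main_s = duration_s - warmup_s

    # --- step sequence -----------------------------------------------------
    warmup_cadence = cadence - 8.0
    # the last warmup step ends at (or just before) the warmup boundary, so
    # every step inside the NF window is already at the main cadence
    n_wu = int(math.floor(warmup_s / (60.0 / warmup_cadence)))
    n_main = int(math.ceil(main_s / (60.0 / cadence))) + 4
    step_nominal = np.concatenate([np.full(n_wu, 60.0 / warmup_cadence),
                                   np.full(n_main, 60.0 / cadence)])
    jitter = base["jitter_sd"] * rng.standard_normal(len(step_nominal))
    durations = step_nominal * np.clip(1.0 + jitter, 0.5, 1.5)
    ic_times = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    keep = ic_times < duration_s
    ic_times, durations = ic_times[keep], durations[keep]
    n_steps = len(ic_times)
    foot_signs = np.where(np.arange(n_steps) % 2 == 0, 1.0, -1.0)

    # --- per-step parameters: warmup scaling, within-trial jitter, fatigue -
    # fatigue ramps linearly from the end of the NF window (first 5 min at
    # the main speed) to the start of the FT window (last complete 5-min
    # block), so the NF window is cleanly unfatigued and the FT window sits
    # entirely on the plateau regardless of where termination falls
    in_warmup = ic_times < warmup_s
    nf_end = warmup_s + 300.0
    ft_start = (math.floor(duration_s / 300.0) - 1) * 300.0
    ramp_len = max(ft_start - nf_end, 1.0)

    def _ramp(t):
        r = np.clip((t - nf_end) / ramp_len, 0.0, 1.0)
        return np.where(t < warmup_s, 0.0, r)

    ramp = _ramp(ic_times)
    per_step = {}
    for k in ("amp_vt", "amp_ml", "amp_ap", "impact_amp", "impact_tau"):
        v = np.full(n_steps, base[k])
        v += ramp * spec.fatigue_effects.get(k, 0.0)
        w = spec.within_trial_sd.get(k, 0.0)
        if w > 0:
            v = v * np.clip(1.0 + w * rng.standard_normal(n_steps), 0.1, None)
        if k != "impact_tau":
            v[in_warmup] *= 0.7
        per_step[k] = np.maximum(v, _param_floor(k))

    # --- assemble the signal ----------------------------------------------
    n_stand = int(round(spec.standing_duration * spec.sampling_rate))
    n_run = int(round(duration_s * spec.sampling_rate))
    t_run = np.arange(n_run) / spec.sampling_rate
    sig = _step_waveforms(t_run, ic_times, durations, per_step, foot_signs)
    noise_sd = np.array([base["noise_vt"], base["noise_ml"], base["noise_ap"]])
    noise = rng.standard_normal((n_run, 3)) * noise_sd
    # fatigue shifts on the noise channels follow the same schedule
    t_ramp = _ramp(t_run)
    for j, k in enumerate(("noise_vt", "noise_ml", "noise_ap")):
        eff = spec.fatigue_effects.get(k, 0.0)
        if eff:
            sd_t = np.maximum(noise_sd[j] + eff * t_ramp, 0.0)
            noise[:, j] = rng.standard_normal(n_run) * sd_t
    sig = sig + noise
    standing = np.tile([1.0, 0.0, 0.0], (n_stand, 1))
    standing = standing + 0.004 * rng.standard_normal((n_stand, 3))
    full = np.vstack([standing, sig])

    # sensor mounting tilt: record in the sensor frame
    rot = _mount_rotation(rng, spec.mount_tilt_sd_deg)
    full = full @ rot.as_matrix()     # world -> sensor via R^T on row vectors
    full = np.clip(full, -16.0, 16.0)

    time = np.arange(len(full)) / spec.sampling_rate - spec.standing_duration

    speed_mlss = subject_effects.get("speed_mlss", spec.speed_mlss_mean)
    rpe_targets = {"MLSS1": (11.3, 15.5), "MLSS2": (11.3, 15.3),
                   "F": (12.3, 16.6), "S": (10.9, 14.2)}
    lo, hi = rpe_targets.get(trial_label, (11.3, 15.5))
    rpe_log = _rpe_schedule(dur_min, rng, lo + 0.8 * rng.standard_normal(), hi + 0.8 * rng.standard_normal())

    return RawTrial(
        subject_id=subject_effects.get("subject_id", "S00"),
        trial_label=trial_label,
        sampling_rate=spec.sampling_rate,
        time=time,
        accel=full,
        speed=spec.speed_for(trial_label, speed_mlss),
        duration=duration_s,
        warmup_duration=warmup_s,
        standing_duration=spec.standing_duration,
        rpe_log=rpe_log,
        true_ic_times=ic_times.copy(),
        cadence=cadence,
    )


def draw_subject_effects(spec: CohortSpec, subject_id: str,
                         rng: np.random.Generator) -> dict:
    """Subject-level trait offsets, drawn once and shared across trials."""
    eff = {k: sd * rng.standard_normal() for k, sd in spec.between_subject_sd.items()}
    eff["subject_id"] = subject_id
    eff["speed_mlss"] = spec.speed_mlss_mean + spec.speed_mlss_sd * rng.standard_normal()
    return eff


def iter_cohort(spec: CohortSpec):
    """Yield the cohort's trials one at a time (n_subjects x len(trial_labels)).

    Randomness is split hierarchically from ``spec.seed``: one stream per
    subject for traits, one per subject-trial for everything else, so the
    cohort is reproducible and any single trial can be regenerated.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    for i, sseq in enumerate(subject_seeds):
        subject_id = f"S{i + 1:02d}"
        streams = sseq.spawn(len(spec.trial_labels) + 1)
        effects = draw_subject_effects(spec, subject_id, np.random.default_rng(streams[0]))
        for j, label in enumerate(spec.trial_labels):
            yield simulate_trial(spec, effects, label, np.random.default_rng(streams[j + 1]))


def simulate_cohort(spec: CohortSpec) -> list:
    """Materialize the full cohort as a list of RawTrial records."""
    return list(iter_cohort(spec))


# ---------------------------------------------------------------------------
# feature-level generator (variance-component model without waveforms)
# ---------------------------------------------------------------------------

def simulate_condition_means(n_subjects: int, rng, *, trial_labels=TRIAL_LABELS,
                             mu: float = 0.0, sigma_subject: float = 1.0,
                             sigma_trial: float = 0.0, sigma_error: float = 1.0,
                             fatigue_shift: float = 0.0) -> pd.DataFrame:
    """Draw a subject x trial x window table of one feature's condition means.

    y_ijw = mu + S_i + T_j + shift*[w = FT] + e_ijw with S ~ N(0, s_subj^2),
    T ~ N(0, s_trial^2) (a systematic trial offset shared by subjects),
    e ~ N(0, s_err^2). This is the measurement model the reliability layer
    assumes; calibration suites (type-I, power, ICC recovery) sample from it.
    """
    rng = np.random.default_rng(rng)
    subj = sigma_subject * rng.standard_normal(n_subjects)
    trial_off = sigma_trial * rng.standard_normal(len(trial_labels))
    rows = []
    for i in range(n_subjects):
        for j, label in enumerate(trial_labels):
            for w in ("NF", "FT"):
                val = (mu + subj[i] + trial_off[j]
                       + (fatigue_shift if w == "FT" else 0.0)
                       + sigma_error * rng.standard_normal())
                rows.append((f"S{i + 1:02d}", label, w, val))
    return pd.DataFrame(rows, columns=["subject", "trial", "window", "value"])


def simulate_icc_matrix(n_subjects: int, k_trials: int, rng, *,
                        sigma_subject: float = 1.0, sigma_error: float = 1.0,
                        sigma_trial: float = 0.0) -> np.ndarray:
    """Subject x trial ratings matrix under the two-way random-effects model."""
    rng = np.random.default_rng(rng)
    s = sigma_subject * rng.standard_normal((n_subjects, 1))
    t = sigma_trial * rng.standard_normal((1, k_trials))
    e = sigma_error * rng.standard_normal((n_subjects, k_trials))
    return s + t + e


# ---------------------------------------------------------------------------
# trial I/O: CSV signal + JSON metadata sidecar
# ---------------------------------------------------------------------------

def trial_basename(trial: RawTrial) -> str:
    return f"{trial.subject_id}_{trial.trial_label}"


def write_trial(trial: RawTrial, outdir) -> Path:
    """Write ``<subject>_<label>.csv`` (time_s,ax_g,ay_g,az_g) plus a JSON
    metadata sidecar; returns the CSV path. This is also the reader contract
    for real recordings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = trial_basename(trial)
    csv_path = outdir / f"{base}.csv"
    df = pd.DataFrame({
        "time_s": np.round(trial.time, 9),
        "ax_g": trial.accel[:, 0],
        "ay_g": trial.accel[:, 1],
        "az_g": trial.accel[:, 2],
    })
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "subject_id": trial.subject_id,
        "trial_label": trial.trial_label,
        "sampling_rate": trial.sampling_rate,
        "speed": trial.speed,
        "duration": trial.duration,
        "warmup_duration": trial.warmup_duration,
        "standing_duration": trial.standing_duration,
        "rpe_log": trial.rpe_log,
        "cadence": trial.cadence,
    }
    if trial.true_ic_times is not None:
        meta["true_ic_times"] = [round(float(x), 9) for x in trial.true_ic_times]
    (outdir / f"{base}.json").write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trial(csv_path) -> RawTrial:
    """Read a trial written by :func:`write_trial` (CSV + JSON sidecar)."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    accel = df[["ax_g", "ay_g", "az_g"]].to_numpy()
    ic = meta.get("true_ic_times")
    return RawTrial(
        subject_id=meta["subject_id"],
        trial_label=meta["trial_label"],
        sampling_rate=meta["sampling_rate"],
        time=df["time_s"].to_numpy(),
        accel=accel,
        speed=meta["speed"],
        duration=meta["duration"],
        warmup_duration=meta["warmup_duration"],
        standing_duration=meta["standing_duration"],
        rpe_log=[tuple(x) for x in meta["rpe_log"]],
        true_ic_times=np.asarray(ic) if ic is not None else None,
        cadence=meta.get("cadence"),
    )
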