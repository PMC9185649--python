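"""Raw trial → fatigue-labeled five-stride samples.

Stages: static attitude correction (align the sensor's mean standing
acceleration with the vertical axis), initial-contact (IC) detection on the
corrected resultant, step/stride segmentation with a ±2 SD step-length
exclusion rule, and windowing into the non-fatigued (NF, first 5 min after
the warmup) and fatigued (FT, last complete 5-min block on the 5-min RPE
grid) conditions. Signals are never filtered; features downstream see raw
(rotated) samples.

Index convention: 0-based, half-open [start, end) everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation

from .synthgait import RawTrial

logger = logging.getLogger(__name__)

WINDOW_S = 300.0          # NF/FT window length, s
RPE_GRID_S = 300.0        # RPE sampling grid, s
STRIDES_PER_SAMPLE = 5


class SegmentationError(RuntimeError):
    """Gait events could not be segmented from the signal."""


class StaticWindowError(ValueError):
    """The requested static window is unusable for attitude correction."""


@dataclass
class OrientationCorrection:
    rotation: np.ndarray            # 3x3 orthonormal, det +1
    static_window: tuple            # (start_s, end_s) on the trial clock
    gravity_estimate: np.ndarray    # mean static acceleration, sensor frame, g

    def apply(self, accel: np.ndarray) -> np.ndarray:
        """Rotate (n, 3) sensor-frame samples into the aligned frame."""
        return np.asarray(accel) @ self.rotation.T


@dataclass
class GaitEvents:
    ic_indices: np.ndarray              # strictly increasing sample indices
    step_bounds: list                   # [(start, end), ...] half-open
    stride_bounds: list                 # [(start, end), ...] half-open
    excluded_steps: list                # indices into step_bounds
    stride_run_id: list = field(default_factory=list)  # contiguity group per stride

    @property
    def retained_steps(self) -> list:
        excl = set(self.excluded_steps)
        return [i for i in range(len(self.step_bounds)) if i not in excl]


@dataclass
class StrideSample:
    """Five consecutive retained strides of corrected acceleration."""

    accel: np.ndarray               # (n, 3) corrected VT/ML/AP, g
    stride_bounds: list             # local half-open bounds of each stride
    window_label: str               # "NF" | "FT"
    subject_id: str
    trial_label: str
    rpe: int

    @property
    def resultant(self) -> np.ndarray:
        return np.linalg.norm(self.accel, axis=1)

    def axis(self, name: str) -> np.ndarray:
        i = {"vt": 0, "ml": 1, "ap": 2}.get(name)
        return self.resultant if name == "res" else self.accel[:, i]


def estimate_attitude_correction(trial: RawTrial, static_window: tuple | None = None,
                                 max_dynamic_sd: float = 0.05) -> OrientationCorrection:
    """Rotation aligning the mean static acceleration with +VT.

    ``static_window`` is (start_s, end_s) on the trial clock; default is the
    standing prelude before the warmup. The rotation is the minimal rotation
    mapping the unit gravity estimate onto (1, 0, 0) — it has no yaw
    component about gravity, so the ML/AP axes are disturbed as little as
    possible. Sample norms are exactly preserved.
    """
    if static_window is None:
        static_window = (-trial.standing_duration, 0.0)
    lo, hi = static_window
    if hi - lo < 0.5:
        raise StaticWindowError("static window must span at least 0.5 s")
    mask = (trial.time >= lo) & (trial.time < hi)
    seg = trial.accel[mask]
    if len(seg) < 2:
        raise StaticWindowError("static window contains no samples")
    mags = np.linalg.norm(seg, axis=1)
    if np.std(mags) > max_dynamic_sd:
        raise StaticWindowError(
            f"static window too dynamic (|a| sd {np.std(mags):.3f} g > "
            f"{max_dynamic_sd} g); choose a quieter window")
    g_hat = seg.mean(axis=0)
    norm = np.linalg.norm(g_hat)
    if norm < 0.5:
        raise StaticWindowError(
            f"mean static acceleration {norm:.3f} g is far from 1 g "
            "(free-fall or corrupt window); cannot estimate gravity")
    rot, _ = Rotation.align_vectors([[1.0, 0.0, 0.0]], [g_hat / norm])
    return OrientationCorrection(rotation=rot.as_matrix(),
                                 static_window=(lo, hi),
                                 gravity_estimate=g_hat)


def detect_initial_contacts(accel: np.ndarray, sampling_rate: float,
                            expected_cadence: float, *, mad_factor: float = 2.0,
                            min_required: int = 10) -> np.ndarray:
    """IC sample indices from the corrected resultant.

    Detects local maxima of the resultant exceeding median + k*MAD with a
    minimum peak separation of half the expected step period. The simulated
    impact transient peaks at the IC itself, so no onset refinement is
    applied; accuracy is validated against simulator ground truth.
    """
    accel = np.asarray(accel)
    res = np.linalg.norm(accel, axis=1) if accel.ndim == 2 else accel
    step_period = 60.0 / expected_cadence
    if len(res) < 10 * step_period * sampling_rate:
        raise SegmentationError("signal shorter than 10 expected steps")
    med = np.median(res)
    mad = np.median(np.abs(res - med))
    height = med + mad_factor * mad
    # peaks closer than 0.7 of a step apart cannot both be ICs; true ICs sit
    # a full step period apart, so this still satisfies the 0.5-period
    # minimum-spacing contract while rejecting mid-step oscillation crests
    distance = max(int(round(0.7 * step_period * sampling_rate)), 1)
    peaks, _ = find_peaks(res, height=height, distance=distance)
    if len(peaks) < min_required:
        raise SegmentationError(
            f"only {len(peaks)} ICs found (< {min_required}); no recognizable gait")
    return peaks.astype(np.int64)


def segment_and_filter_steps(ic_indices: np.ndarray, sampling_rate: float) -> GaitEvents:
    """Steps from consecutive ICs; exclude steps whose length (in samples)
    lies beyond ±2 SD of the mean; strides from pairs of consecutive
    retained steps.

    The mean and SD are computed once over all steps before any exclusion
    (population SD; SD = 0 means no exclusions). Left/right feet cannot be
    identified from a single CoM sensor, so ICs are alternately assigned:
    within each maximal run of consecutive retained steps, strides pair
    steps (0,1), (2,3), ... — an excluded step splits the stream, so no
    stride or five-stride sample ever spans the gap.
    """
    ic = np.asarray(ic_indices, dtype=np.int64)
    if len(ic) < 10:
        raise SegmentationError("need at least 10 ICs to segment steps")
    if np.any(np.diff(ic) <= 0):
        raise SegmentationError("IC indices must be strictly increasing")
    lengths = np.diff(ic).astype(float)
    mean, sd = lengths.mean(), lengths.std()       # population SD, pre-exclusion
    if sd == 0:
        excluded = np.zeros(len(lengths), dtype=bool)
    else:
        excluded = np.abs(lengths - mean) > 2.0 * sd
    if excluded.mean() > 0.5:
        logger.warning("%.0f%% of steps excluded by the ±2 SD rule",
                       100 * excluded.mean())
    step_bounds = [(int(ic[i]), int(ic[i + 1])) for i in range(len(lengths))]
    excluded_steps = list(np.flatnonzero(excluded))

    stride_bounds, run_ids = [], []
    run_start = None
    run_id = -1
    retained = ~excluded
    for i in range(len(lengths) + 1):
        if i < len(lengths) and retained[i]:
            if run_start is None:
                run_start = i
                run_id += 1
        else:
            if run_start is not None:
                run = list(range(run_start, i))
                for j in range(0, len(run) - 1, 2):
                    a, b = run[j], run[j + 1]
                    stride_bounds.append((step_bounds[a][0], step_bounds[b][1]))
                    run_ids.append(run_id)
                run_start = None
    if not stride_bounds:
        raise SegmentationError("zero retained strides after the ±2 SD exclusion")
    return GaitEvents(ic_indices=ic, step_bounds=step_bounds,
                      stride_bounds=stride_bounds, excluded_steps=excluded_steps,
                      stride_run_id=run_ids)


def condition_windows(trial: RawTrial) -> dict:
    """NF and FT window bounds in seconds on the trial clock.

    NF starts when the main speed begins (warmup excluded) and spans 5 min.
    FT is the last complete 5-min block on the RPE grid; e.g. termination at
    38 min gives FT = [30, 35] min, termination at exactly 45 min gives
    [40, 45] min.
    """
    nf = (trial.warmup_duration, trial.warmup_duration + WINDOW_S)
    n_blocks = int(np.floor(trial.duration / RPE_GRID_S + 1e-9))
    ft = ((n_blocks - 1) * RPE_GRID_S, n_blocks * RPE_GRID_S)
    if ft[0] < nf[1] - 1e-9:
        raise ValueError(
            f"NF {tuple(round(x / 60, 2) for x in nf)} min and FT "
            f"{tuple(round(x / 60, 2) for x in ft)} min windows overlap; "
            "trial too short")
    return {"NF": nf, "FT": ft}


def _samples_in_window(trial: RawTrial, corrected: np.ndarray,
                       ic_indices: np.ndarray, window: tuple, label: str) -> tuple:
    """Segment one window's ICs and group retained strides into five-stride
    samples; returns (samples, diagnostics dict)."""
    rate = trial.sampling_rate
    offset = int(round(trial.standing_duration * rate))   # trial clock t=0 index
    lo = offset + int(round(window[0] * rate))
    hi = offset + int(round(window[1] * rate))
    in_win = ic_indices[(ic_indices >= lo) & (ic_indices < hi)]
    diag = {"n_ics": int(len(in_win)), "n_steps_excluded": 0,
            "n_strides": 0, "n_samples": 0}
    if len(in_win) < 10:
        return [], diag
    events = segment_and_filter_steps(in_win, rate)
    diag["n_steps_excluded"] = len(events.excluded_steps)
    diag["n_strides"] = len(events.stride_bounds)
    rpe = trial.rpe_at(window[1] / 60.0)

    samples = []
    bounds, runs = events.stride_bounds, events.stride_run_id
    i = 0
    while i + STRIDES_PER_SAMPLE <= len(bounds):
        group = bounds[i:i + STRIDES_PER_SAMPLE]
        grp_runs = runs[i:i + STRIDES_PER_SAMPLE]
        contiguous = (len(set(grp_runs)) == 1 and
                      all(group[j][1] == group[j + 1][0] for j in range(len(group) - 1)))
        if not contiguous:
            i += 1       # advance past the break; never span an exclusion gap
            continue
        s0, s1 = group[0][0], group[-1][1]
        local = [(a - s0, b - s0) for a, b in group]
        samples.append(StrideSample(accel=corrected[s0:s1], stride_bounds=local,
                                    window_label=label, subject_id=trial.subject_id,
                                    trial_label=trial.trial_label, rpe=rpe))
        i += STRIDES_PER_SAMPLE
    diag["n_samples"] = len(samples)
    return samples, diag


def extract_condition_windows(trial: RawTrial, events: GaitEvents | np.ndarray,
                              corrected: np.ndarray) -> tuple:
    """(NF samples, FT samples) from a corrected trial and its detected ICs.

    The ±2 SD step exclusion is applied within each window (mean/SD over
    that window's steps), and non-overlapping consecutive groups of five
    retained strides become samples carrying the window's RPE label.
    """
    if trial.duration < trial.warmup_duration + 600.0 - 1e-9:
        raise ValueError("trial duration < warmup + 10 min: windows would overlap")
    ic = events.ic_indices if isinstance(events, GaitEvents) else np.asarray(events)
    windows = condition_windows(trial)
    nf, _ = _samples_in_window(trial, corrected, ic, windows["NF"], "NF")
    ft, _ = _samples_in_window(trial, corrected, ic, windows["FT"], "FT")
    return nf, ft


def preprocess_trial(trial: RawTrial, static_window: tuple | None = None,
                     expected_cadence: float | None = None) -> tuple:
    """Full chain: attitude correction → IC detection → NF/FT five-stride
    samples. Returns (nf_samples, ft_samples, diagnostics)."""
    corr = estimate_attitude_correction(trial, static_window)
    corrected = corr.apply(trial.accel)
    cadence = expected_cadence or trial.cadence or 170.0
    run_mask = trial.time >= 0
    offset = int(np.argmax(run_mask))
    ic = detect_initial_contacts(corrected[run_mask], trial.sampling_rate, cadence)
    ic = ic + offset
    windows = condition_windows(trial)
    diag = {"subject": trial.subject_id, "trial": trial.trial_label,
            "duration_min": trial.duration / 60.0, "n_ics_total": int(len(ic))}
    out = {}
    for label in ("NF", "FT"):
        out[label], wdiag = _samples_in_window(trial, corrected, ic,
                                               windows[label], label)
        diag.update({f"{k}_{label.lower()}": v for k, v in wdiag.items()})
    return out["NF"], out["FT"], diag


def events_table(events: GaitEvents) -> pd.DataFrame:
    """Debug table: one row per step with its length and retained flag."""
    lengths = np.diff(events.ic_indices)
    excl = set(events.excluded_steps)
    return pd.DataFrame({
        "ic_index": events.ic_indices[:-1],
        "step_length": lengths,
        "retained": [i not in excl for i in range(len(lengths))],
    })
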