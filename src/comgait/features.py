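"""Per-sample feature extraction: 39 features per five-stride sample.

Nine statistics (mean, SD, median, 25th/75th percentile, RMS, max, min,
sample entropy) on each of the four signals (VT, ML, AP and the resultant
RES) give 36 values; the three RMS ratios (single-axis RMS over resultant
RMS) complete the 39. All values are in g except sample entropy and the
RMS ratios, which are dimensionless.

Sample entropy follows Richman & Moorman: SampEn(m, r) = -ln(A/B) with B
the number of ordered template pairs of length m within Chebyshev distance
r (self-matches excluded), A the same at length m+1; both counts use the
first N-m templates. The tolerance is r x SD of the segment, so the measure
is amplitude-scale invariant. Following the gait-cycle (rather than
time-sample) convention, each stride is linearly resampled to a fixed
number of points before concatenation, making the entropy input commensurate
across cadences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import StrideSample

logger = logging.getLogger(__name__)

AXES = ("vt", "ml", "ap", "res")
BASIC_STATS = ("mean", "sd", "median", "p25", "p75", "rms", "max", "min")
STATS = BASIC_STATS + ("se",)

#: the 39 canonical feature names, <stat>_<axis> plus the three RMS ratios
FEATURE_NAMES = tuple(f"{s}_{a}" for a in AXES for s in STATS) + \
    ("rmsr_vt", "rmsr_ml", "rmsr_ap")

DEFAULT_SE_PARAMS = {"m": 2, "r": 0.2, "points_per_stride": 200}

_SE_STABLE_N = 2000
_warned_short_se = False


@dataclass
class FeatureVector:
    """The 39 named feature values for one five-stride sample."""

    values: dict
    subject_id: str = ""
    trial_label: str = ""
    window_label: str = ""
    rpe: int | None = None

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        if len(self.values) != len(FEATURE_NAMES):
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(f"unexpected features: {sorted(extra)}")

    def __getitem__(self, name):
        return self.values[name]

    def to_row(self) -> dict:
        row = {"subject": self.subject_id, "trial": self.trial_label,
               "window": self.window_label, "rpe": self.rpe}
        row.update({k: self.values[k] for k in FEATURE_NAMES})
        return row


def compute_basic_stats(segment: np.ndarray) -> dict:
    """Mean, sample SD (n-1), median, 25th/75th percentile (linear
    interpolation), RMS, max and min of one axis segment."""
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    if np.all(np.isnan(x)):
        raise ValueError("segment is all-NaN")
    if np.any(np.isnan(x)):
        raise ValueError("segment contains NaN")
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "median": float(np.median(x)),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
    }


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple:
    """Vectorized template-match counts (B at length m, A at m+1)."""
    n = len(x)
    nt = n - m          # number of templates used at both lengths
    if nt < 2:
        return 0, 0
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    emb_m = emb_m1[:, :m]
    b = a = 0
    block = max(1, int(4e6 // max(nt, 1)))
    for s in range(0, nt, block):
        chunk = emb_m[s:s + block]
        d_m = np.max(np.abs(chunk[:, None, :] - emb_m[None, :, :]), axis=2)
        within = d_m <= r
        b += int(within.sum()) - len(chunk)          # remove self-matches
        chunk1 = emb_m1[s:s + block]
        d_m1 = np.max(np.abs(chunk1[:, None, :] - emb_m1[None, :, :]), axis=2)
        within1 = d_m1 <= r
        a += int(within1.sum()) - len(chunk1)
    return a, b


try:                                   # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _sampen_counts_jit(x, m, r):   # pragma: no cover
        n = len(x)
        nt = n - m
        a = 0
        b = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                if d <= r:
                    b += 1
                    diff = abs(x[i + m] - x[j + m])
                    if diff > d:
                        d = diff
                    if d <= r:
                        a += 1
        return a, b

    def _sampen_counts(x, m, r):
        a, b = _sampen_counts_jit(x, m, r)
        return 2 * a, 2 * b            # ordered pairs, as in the definition

except ImportError:                    # pragma: no cover
    def _sampen_counts(x, m, r):
        return _sampen_counts_numpy(x, m, r)


def sample_entropy(segment: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r x SD) of a 1-D segment; NaN flags undefined entropy.

    Returns NaN (a flagged sentinel, logged) when no template matches exist
    at either length, rather than returning infinity.
    """
    x = np.asarray(segment, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if r <= 0:
        raise ValueError("r must be > 0")
    if len(x) <= m + 1:
        raise ValueError(f"segment length {len(x)} too short for m = {m}")
    tol = r * float(np.std(x))
    a, b = _sampen_counts(x, m, tol)
    if b == 0 or a == 0:
        logger.info("sample entropy undefined (A=%d, B=%d, n=%d); flagged NaN",
                    a, b, len(x))
        return float("nan")
    return float(-np.log(a / b))


def gait_cycle_normalize(segment: np.ndarray, stride_bounds,
                         points_per_stride: int = 200) -> np.ndarray:
    """Resample each stride to a fixed number of points and concatenate,
    so entropy sees the signal on a gait-cycle (0-100% of stride) base."""
    x = np.asarray(segment, dtype=float)
    out = []
    grid = np.linspace(0.0, 1.0, points_per_stride, endpoint=False)
    for a, b in stride_bounds:
        stride = x[a:b]
        src = np.linspace(0.0, 1.0, len(stride), endpoint=False)
        out.append(np.interp(grid, src, stride))
    return np.concatenate(out)


def compute_sample_entropy(segment: np.ndarray, stride_bounds=None, m: int = 2,
                           r: float = 0.2, points_per_stride: int = 200) -> float:
    """Sample entropy of one axis of a five-stride sample.

    With ``stride_bounds`` given, the gait-cycle approach is used: each
    stride is linearly resampled to ``points_per_stride`` points before the
    entropy computation. Pass ``stride_bounds=None`` for raw-time entropy
    (sensitivity checks).
    """
    global _warned_short_se
    if stride_bounds is not None:
        segment = gait_cycle_normalize(segment, stride_bounds, points_per_stride)
    if len(segment) < _SE_STABLE_N and not _warned_short_se:
        logger.warning(
            "sample-entropy input has %d points (< %d, where SampEn is fully "
            "stable); gait-cycle normalization keeps it commensurate across "
            "samples — raise points_per_stride for a denser input "
            "(warning shown once)", len(segment), _SE_STABLE_N)
        _warned_short_se = True
    return sample_entropy(segment, m=m, r=r)


def compute_rmsr(rms_vt: float, rms_ml: float, rms_ap: float,
                 rms_res: float) -> tuple:
    """Single-axis RMS over resultant RMS; each ratio lies in (0, 1]."""
    if rms_res <= 0:
        raise ValueError("resultant RMS must be > 0 (degenerate all-zero signal)")
    return rms_vt / rms_res, rms_ml / rms_res, rms_ap / rms_res


def extract_features(sample: StrideSample, se_params: dict | None = None) -> FeatureVector:
    """The full 39-value feature vector for one five-stride sample."""
    p = {**DEFAULT_SE_PARAMS, **(se_params or {})}
    values = {}
    rms = {}
    for ax in AXES:
        seg = sample.axis(ax)
        stats = compute_basic_stats(seg)
        for k, v in stats.items():
            values[f"{k}_{ax}"] = v
        rms[ax] = stats["rms"]
        values[f"se_{ax}"] = compute_sample_entropy(
            seg, sample.stride_bounds, m=p["m"], r=p["r"],
            points_per_stride=p["points_per_stride"])
    rv, rm, ra = compute_rmsr(rms["vt"], rms["ml"], rms["ap"], rms["res"])
    values.update({"rmsr_vt": rv, "rmsr_ml": rm, "rmsr_ap": ra})
    return FeatureVector(values=values, subject_id=sample.subject_id,
                         trial_label=sample.trial_label,
                         window_label=sample.window_label, rpe=sample.rpe)


def feature_table(vectors) -> pd.DataFrame:
    """Wide per-sample table: one row per sample, 39 named feature columns."""
    rows = []
    for i, v in enumerate(vectors):
        row = v.to_row()
        row["sample_idx"] = i
        rows.append(row)
    cols = ["subject", "trial", "window", "sample_idx", "rpe", *FEATURE_NAMES]
    return pd.DataFrame(rows)[cols]


def feature_table_long(vectors) -> pd.DataFrame:
    """Long-format table: subject, trial, window, sample_idx, feature, value."""
    wide = feature_table(vectors)
    return wide.melt(id_vars=["subject", "trial", "window", "sample_idx"],
                     value_vars=list(FEATURE_NAMES),
                     var_name="feature", value_name="value")


def aggregate_condition_means(vectors) -> pd.DataFrame:
    """Per subject x trial x window mean of each feature.

    NaN-flagged sample-entropy values are excluded from that feature's mean
    (with a logged count); an empty group raises. Adds ``n_samples`` and
    ``n_strides`` bookkeeping columns.
    """
    if not vectors:
        raise ValueError("no feature vectors to aggregate")
    wide = feature_table(vectors)
    n_dropped = int(wide[list(FEATURE_NAMES)].isna().sum().sum())
    if n_dropped:
        logger.info("excluding %d undefined (NaN) feature values from means", n_dropped)
    grouped = wide.groupby(["subject", "trial", "window"], sort=True)
    means = grouped[list(FEATURE_NAMES)].mean()          # skips NaN per feature
    means["n_samples"] = grouped.size()
    means["n_strides"] = grouped.size() * 5
    if (means["n_samples"] < 1).any():
        bad = means.index[means["n_samples"] < 1].tolist()
        raise ValueError(f"empty subject/trial/window groups: {bad}")
    return means.reset_index()
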