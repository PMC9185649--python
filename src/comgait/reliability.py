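"""The statistical layer: repeated-measures ANOVAs, ICC(2,k) reliability,
paired RPE tests and the maximal-lactate-steady-state (MLSS) rule.

The design is fully within-subject: every runner contributes every
trial x fatigue-state cell, so the two-way fatigue x trial ANOVA and the
one-way trial-variable ANOVA are repeated-measures models (subject as the
random blocking factor), and reliability is the two-way random-effects,
absolute-agreement, average-measures intraclass correlation ICC(2,k) of
Shrout & Fleiss:

    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

with MSR the between-subjects mean square, MSC the between-trials mean
square, MSE the residual, and n the number of subjects. Interpretation
bins: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >= 0.9 excellent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
MM_TRIALS = ("MLSS1", "MLSS2")


@dataclass
class AnovaResult:
    feature: str
    method: str                 # "MM" | "ALL" | "" for trial variables
    effect: str                 # "fatigue_state" | "trial" | "interaction"
    F: float
    df: tuple
    p: float
    direction: str = "none"     # "+" | "-" | "none"


@dataclass
class IccResult:
    feature: str
    method: str
    window: str                 # "NF" | "FT"
    icc: float
    category: str
    n_subjects: int
    k_trials: int
    degenerate: bool = False


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def icc_category(icc: float) -> str:
    if np.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_2k(ratings, feature: str = "", method: str = "",
           window: str = "") -> IccResult:
    """ICC(2,k) of a subject x trial ratings matrix.

    Rows with any missing cell are dropped first (listwise deletion,
    logged). Requires >= 3 complete subjects and >= 2 trials. A
    non-positive denominator is flagged degenerate (icc = NaN).
    """
    mat = np.asarray(pd.DataFrame(ratings), dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("ratings must be a 2-D matrix with >= 2 trials")
    complete = ~np.isnan(mat).any(axis=1)
    if (~complete).any():
        logger.info("ICC: dropping %d incomplete subjects", int((~complete).sum()))
    mat = mat[complete]
    n, k = mat.shape
    if n < 3:
        raise ValueError(f"need >= 3 complete subjects for ICC, got {n}")
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((mat - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom <= 0:
        logger.warning("ICC degenerate: MSR + (MSC - MSE)/n = %.3g <= 0", denom)
        return IccResult(feature, method, window, float("nan"), "undefined",
                         n, k, degenerate=True)
    icc = (msr - mse) / denom
    return IccResult(feature, method, window, float(icc), icc_category(icc), n, k)


def _complete_subjects(df: pd.DataFrame, cells: list) -> pd.DataFrame:
    """Listwise deletion: keep subjects holding every required cell exactly
    once; raise if none are left or duplicates make cells ambiguous."""
    ok, dropped = [], []
    for subj, g in df.groupby("subject"):
        have = set(map(tuple, g[["trial", "window"]].drop_duplicates().values)) \
            if "window" in g else set(g["trial"])
        need = set(cells)
        if need <= have and len(g) == len(g.drop_duplicates(
                subset=[c for c in ("trial", "window") if c in g])):
            ok.append(subj)
        else:
            dropped.append(subj)
    if dropped:
        logger.info("dropping incomplete subjects: %s", dropped)
    if not ok:
        raise ValueError(f"no complete subjects remain; dropped {dropped}")
    return df[df["subject"].isin(ok)].copy()


def _f_test(ss_eff, df_eff, ss_err, df_err, scale) -> tuple:
    """F and p with explicit degenerate conventions: a zero error mean
    square gives F = 0, p = 1 when the effect is also zero (nothing to
    detect) and F = inf, p = 0 when it is not (a perfectly replicated
    effect)."""
    tiny = 1e-12 * max(scale, 1e-300)
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err <= tiny:
        if ms_eff <= tiny:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = ms_eff / ms_err
    return float(f), float(sps.f.sf(f, df_eff, df_err))


def rm_anova_two_way(cells: np.ndarray) -> dict:
    """Balanced two-way within-subject ANOVA from cell data.

    ``cells`` has shape (n_subjects, n_A, n_B) with one observation per
    subject x A x B cell. Each main effect and the interaction is tested
    against its own subject-by-effect interaction mean square (the
    univariate repeated-measures partition). Returns
    {effect: (F, (df_num, df_den), p)} for "A", "B", "A:B".
    """
    y = np.asarray(cells, dtype=float)
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_sab = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb
    ss_sab = max(ss_sab, 0.0)
    out = {}
    scale = ss_tot
    out["A"] = _wrap_f(*_f_test(ss_a, a - 1, ss_sa, (n - 1) * (a - 1), scale),
                       a - 1, (n - 1) * (a - 1))
    out["B"] = _wrap_f(*_f_test(ss_b, b - 1, ss_sb, (n - 1) * (b - 1), scale),
                       b - 1, (n - 1) * (b - 1))
    out["A:B"] = _wrap_f(*_f_test(ss_ab, (a - 1) * (b - 1), ss_sab,
                                  (n - 1) * (a - 1) * (b - 1), scale),
                         (a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1))
    return out


def _wrap_f(f, p, df_num, df_den):
    return f, (float(df_num), float(df_den)), p


def rm_anova_one_way(cells: np.ndarray) -> tuple:
    """Balanced one-way within-subject ANOVA; ``cells`` is (n_subjects,
    n_levels). Returns (F, (df_num, df_den), p)."""
    y = np.asarray(cells, dtype=float)
    n, a = y.shape
    if n < 2 or a < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    grand = y.mean()
    m_s = y.mean(axis=1)
    m_a = y.mean(axis=0)
    ss_a = n * np.sum((m_a - grand) ** 2)
    ss_err = np.sum((y - m_s[:, None] - m_a[None, :] + grand) ** 2)
    f, p = _f_test(ss_a, a - 1, ss_err, (n - 1) * (a - 1),
                   np.sum((y - grand) ** 2))
    return f, (float(a - 1), float((n - 1) * (a - 1))), p


def _cells_array(data: pd.DataFrame, trials, windows=("NF", "FT")) -> np.ndarray:
    """(n_subjects, n_windows, n_trials) cell array from a long table."""
    pivot = data.pivot_table(index="subject", columns=["window", "trial"],
                             values="value", aggfunc="mean")
    subs = pivot.index
    arr = np.empty((len(subs), len(windows), len(trials)))
    for i, w in enumerate(windows):
        for j, t in enumerate(trials):
            arr[:, i, j] = pivot[(w, t)].to_numpy()
    return arr


def two_way_fatigue_trial_anova(df: pd.DataFrame, method: str,
                                feature: str = "",
                                alpha: float = ALPHA_DEFAULT) -> list:
    """Within-subject two-way ANOVA, fatigue state (NF/FT) x trial.

    ``df`` is long: columns subject, trial, window, value. ``method`` "MM"
    restricts trials to MLSS1/MLSS2; "ALL" uses all four. Returns the three
    effects; the fatigue effect carries the sign of (FT - NF) grand means
    when significant at ``alpha``.
    """
    if method not in ("MM", "ALL"):
        raise ValueError("method must be 'MM' or 'ALL'")
    data = df.copy()
    if method == "MM":
        data = data[data["trial"].isin(MM_TRIALS)]
    trials = sorted(data["trial"].unique())
    cells = [(t, w) for t in trials for w in ("NF", "FT")]
    data = _complete_subjects(data.dropna(subset=["value"]), cells)
    arr = _cells_array(data, trials)
    res = rm_anova_two_way(arr)
    ft = arr[:, 1, :].mean()
    nf = arr[:, 0, :].mean()
    out = []
    for key, effect in (("A", "fatigue_state"), ("B", "trial"),
                        ("A:B", "interaction")):
        f, dfp, p = res[key]
        direction = "none"
        if effect == "fatigue_state" and p < alpha:
            direction = "+" if ft - nf > 0 else "-"
        out.append(AnovaResult(feature=feature, method=method, effect=effect,
                               F=f, df=dfp, p=p, direction=direction))
    return out


def trial_variable_anova(df: pd.DataFrame, variable: str = "",
                         alpha: float = ALPHA_DEFAULT) -> AnovaResult:
    """One-way repeated-measures ANOVA of a trial variable across trials.

    ``df`` is long with columns subject, trial, value.
    """
    data = df.dropna(subset=["value"])
    trials = sorted(data["trial"].unique())
    if len(trials) < 2:
        raise ValueError("need >= 2 trials")
    data = _complete_subjects(data, trials)
    if data["subject"].nunique() < 3:
        raise ValueError("need >= 3 complete subjects")
    mat = data.pivot_table(index="subject", columns="trial", values="value",
                           aggfunc="mean")[trials].to_numpy()
    f, dfp, p = rm_anova_one_way(mat)
    return AnovaResult(feature=variable, method="", effect="trial",
                       F=f, df=dfp, p=p)


def paired_rpe_test(rpe_nf, rpe_ft) -> PairedTestResult:
    """Two-sided paired t-test between the NF and FT RPE of one trial."""
    a = np.asarray(rpe_nf, dtype=float)
    b = np.asarray(rpe_ft, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need >= 3 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing pairs are not allowed")
    diff = b - a
    dfree = len(a) - 1
    if np.std(diff, ddof=1) == 0:
        logger.warning("paired t-test degenerate: zero variance of differences")
        if np.allclose(diff, 0):
            return PairedTestResult(0.0, dfree, 1.0, degenerate=True)
        t = float(np.inf) * np.sign(diff.mean())
        return PairedTestResult(t, dfree, 0.0, degenerate=True)
    t, p = sps.ttest_rel(b, a)
    return PairedTestResult(float(t), dfree, float(p))


def identify_mlss(lactate_10min: float, lactate_30min: float,
                  completed_30min: bool) -> str:
    """MLSS criterion: 'steady' iff >= 30 min completed and the blood-lactate
    rise between minutes 10 and 30 is < 1 mmol/L."""
    for v in (lactate_10min, lactate_30min):
        if v is None or not np.isfinite(v):
            raise ValueError("missing lactate measurement")
        if v < 0:
            raise ValueError("lactate concentration must be non-negative")
    steady = bool(completed_30min) and (lactate_30min - lactate_10min) < 1.0
    return "steady" if steady else "not_steady"


def icc_matrix_from_means(means: pd.DataFrame, feature: str, window: str,
                          trials) -> pd.DataFrame:
    """Pivot a condition-means table into the subject x trial ratings matrix
    for one feature and fatigue window."""
    sub = means[means["window"] == window]
    mat = sub.pivot(index="subject", columns="trial", values=feature)
    return mat.reindex(columns=list(trials))
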