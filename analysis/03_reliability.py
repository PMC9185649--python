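#!/usr/bin/env python
"""Fatigue-state x trial ANOVA and ICC(2,k) reliability per feature.

Aggregates the per-sample feature table to subject x trial x window means,
then for both comparison methods (MM: the two same-speed MLSS trials;
ALL: all four trials) runs the within-subject two-way ANOVA per feature
and the two-way random-effects absolute-agreement average-measures ICC per
feature and fatigue window. Prints the headline pattern: how many features
show a fatigue main effect, the chance-expectation diagnostic, and the
mean ICC per window x method with its interpretation.
"""

import argparse
from pathlib import Path

import pandas as pd

from comgait import (FEATURE_NAMES, expected_chance_significances,
                     icc_category, icc_2k, two_way_fatigue_trial_anova)
from comgait.reliability import MM_TRIALS, icc_matrix_from_means
from comgait.pipeline import METHOD_TRIALS, feature_axis

ap = argparse.ArgumentParser()
ap.add_argument("--features", type=Path,
                default=Path("results/analysis/features_wide.csv"))
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
ap.add_argument("--alpha", type=float, default=0.05)
args = ap.parse_args()

wide = pd.read_csv(args.features)
means = wide.groupby(["subject", "trial", "window"], as_index=False)[
    list(FEATURE_NAMES)].mean()

anova_rows, icc_rows = [], []
for method, trials in METHOD_TRIALS.items():
    sub = means[means["trial"].isin(trials)]
    for fname in FEATURE_NAMES:
        long = sub.rename(columns={fname: "value"})[
            ["subject", "trial", "window", "value"]]
        for r in two_way_fatigue_trial_anova(long, method, feature=fname,
                                             alpha=args.alpha):
            anova_rows.append({"axis": feature_axis(fname), "feature": fname,
                               "method": method, "effect": r.effect,
                               "F": r.F, "p": r.p, "direction": r.direction})
        for window in ("NF", "FT"):
            res = icc_2k(icc_matrix_from_means(sub, fname, window, trials),
                         feature=fname, method=method, window=window)
            icc_rows.append({"axis": feature_axis(fname), "feature": fname,
                             "method": method, "window": window,
                             "icc": res.icc, "category": res.category})

anova = pd.DataFrame(anova_rows)
icc = pd.DataFrame(icc_rows)
anova.to_csv(args.outdir / "anova_effects.csv", index=False)
icc.to_csv(args.outdir / "icc.csv", index=False)

fat = anova[anova["effect"] == "fatigue_state"]
n_sig = int((fat["p"] < args.alpha).sum())
expected, rounded = expected_chance_significances(len(fat), args.alpha)
print(f"fatigue main effects: {n_sig}/{len(fat)} significant at "
      f"alpha={args.alpha} (chance expectation {expected:.1f} ~ {rounded})")
inter = anova[(anova["effect"] == "interaction") & (anova["p"] < args.alpha)]
print(f"significant fatigue x trial interactions: {len(inter)}"
      + (f" ({', '.join(inter.feature + '/' + inter.method)})" if len(inter) else ""))
for (method, window), g in icc.groupby(["method", "window"]):
    m, med = g["icc"].mean(), g["icc"].median()
    # features with near-zero between-subject variance (e.g. the ML mean,
    # which is ~0 by symmetry) can take large negative ICCs at small n and
    # drag the mean; the median is the robust summary for small cohorts
    print(f"ICC(2,k) {window}_{method}: mean {m:.3f} +- {g['icc'].std():.3f}, "
          f"median {med:.3f} [{icc_category(med)}]")
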