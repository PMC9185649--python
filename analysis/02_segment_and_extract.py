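#!/usr/bin/env python
"""Segment the cohort's trials and extract the 39 features per sample.

For every trial: static attitude correction, initial-contact detection on
the corrected resultant, ±2 SD step-length exclusion, five-stride samples
from the non-fatigued (first 5 min after warmup) and fatigued (last
complete 5-min block) windows, then the 39-feature vector per sample.
Writes results/analysis/features_wide.csv and a per-trial diagnostics
table mirroring the trial-variable summary (strides used, durations, RPE).
"""

import argparse
from pathlib import Path

import pandas as pd

from comgait import extract_features, feature_table, preprocess_trial, read_trial

ap = argparse.ArgumentParser()
ap.add_argument("--indir", type=Path, default=Path("results/cohort"))
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

vectors, diags = [], []
for csv in sorted(args.indir.glob("*.csv")):
    trial = read_trial(csv)
    nf, ft, diag = preprocess_trial(trial)
    vectors += [extract_features(s) for s in nf + ft]
    diags.append(diag)
    print(f"{trial.subject_id} {trial.trial_label:5s} "
          f"ICs {diag['n_ics_total']:5d}  strides NF/FT "
          f"{diag['n_strides_nf']:3d}/{diag['n_strides_ft']:3d}  "
          f"samples {diag['n_samples_nf']:2d}/{diag['n_samples_ft']:2d}")

wide = feature_table(vectors)
wide.to_csv(args.outdir / "features_wide.csv", index=False)
pd.DataFrame(diags).to_csv(args.outdir / "trial_diagnostics.csv", index=False)

print(f"\n{len(wide)} five-stride samples, 39 features each "
      f"-> {args.outdir / 'features_wide.csv'}")
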