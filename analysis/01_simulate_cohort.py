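#!/usr/bin/env python
"""Simulate a demonstration cohort of fatiguing treadmill runs.

Writes one CSV signal file plus JSON metadata sidecar per trial under
results/cohort/ — four trials per runner (MLSS1, MLSS2, 5% faster, 5%
slower), each with a 2 s standing prelude, 5-min warmup and a fatigue ramp.
The demonstration cohort is kept small (8 runners, 125 Hz, ~15-min trials)
so the whole analysis chain in 02/03 reruns in a couple of minutes;
scripts/acceptance.py runs the full 16-runner configuration at 1125 Hz.
"""

import argparse
from pathlib import Path

from comgait import CohortSpec, iter_cohort, write_trial

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
args = ap.parse_args()

spec = CohortSpec(n_subjects=8, sampling_rate=125.0, trial_duration=15.5,
                  trial_duration_sd=0.3, seed=args.seed)

n = 0
for trial in iter_cohort(spec):
    write_trial(trial, args.outdir)
    n += 1
    print(f"{trial.subject_id} {trial.trial_label:5s} "
          f"speed {trial.speed:.2f} m/s, {trial.duration / 60:.1f} min, "
          f"RPE {trial.rpe_log[0][1]} -> {trial.rpe_log[-1][1]}")

print(f"\nwrote {n} trials ({spec.n_subjects} runners x "
      f"{len(spec.trial_labels)} trials) to {args.outdir}")
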