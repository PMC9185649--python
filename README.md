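# comgait

Day-to-day reliability of center-of-mass IMU features during fatiguing
treadmill runs.

Single-trial IMU studies of running fatigue implicitly assume that a
runner's fatigued gait is reproducible across days. `comgait` implements
the analysis that tests this assumption on a repeated-measures design:
each runner performs four constant-speed treadmill trials — two at the
speed associated with maximal lactate steady state (MLSS1, MLSS2), one 5%
faster (F) and one 5% slower (S) — wearing a tri-axial accelerometer at
the center of mass (VT/ML/AP axes, 1125 Hz, ±16 g, units of g). The
package is aimed at wearable-sensor biomechanists and methodologists who
want the full chain as tested, reusable code:

1. **synthgait** — a synthetic cohort generator: periodic running
   acceleration with an impact transient at each initial contact,
   subject/trial/stride variance components, configurable fatigue-state
   effects, protocol structure (standing prelude, 5-min warmup at
   1.92 m/s, RPE every 5 min, 45-min cap). No download needed; every
   stage is testable against simulator ground truth.
2. **preprocess** — static attitude correction (aligns the standing
   gravity vector with +VT), initial-contact detection on the corrected
   resultant, step/stride segmentation with the ±2 SD step-length
   exclusion, and windowing into the non-fatigued (first 5 min at the
   main speed) and fatigued (last complete 5-min block) conditions, cut
   into five-stride samples. Signals are never filtered.
3. **features** — 39 features per sample: mean, SD, median, 25th/75th
   percentile, RMS, max, min and sample entropy on each of VT, ML, AP and
   the resultant, plus the three RMS ratios RMSR = RMS_axis/RMS_RES.
   Sample entropy is SampEn(m=2, r=0.2·SD) on a gait-cycle base (each
   stride resampled to 200 points).
4. **reliability** — within-subject two-way ANOVA (fatigue state × trial)
   per feature under two comparison methods (MM: MLSS1 vs MLSS2; ALL: all
   four trials), one-way trial-variable ANOVAs, paired NF/FT RPE t-tests,
   the MLSS blood-lactate rule, and test–retest reliability as the
   two-way random-effects absolute-agreement average-measures intraclass
   correlation

       ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

   with interpretation bins < 0.5 / 0.5–0.75 / 0.75–0.9 / ≥ 0.9 read as
   poor / moderate / good / excellent.
5. **pipeline** — seeded, deterministic orchestration of the above with
   CSV/JSON table writers and a thin `comgait` CLI
   (`simulate`/`extract`/`analyze`/`all`).

See `docs/methods.md` for the models, parameter defaults and the design
decisions behind them.

## Worked example

The numbered scripts under `analysis/` run the complete analysis on a
demonstration cohort (8 runners, 125 Hz, ~15-min trials):

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort/*.csv + .json
python analysis/02_segment_and_extract.py  # 39 features per five-stride sample
python analysis/03_reliability.py          # ANOVA + ICC tables and headline
python analysis/04_calibration.py          # statistical-layer calibration
```

The third script prints (seed 1):

```
fatigue main effects: 74/78 significant at alpha=0.05 (chance expectation 3.9 ~ 4)
significant fatigue x trial interactions: 5 (median_ap/MM, min_ap/MM, min_res/MM, p25_ml/ALL, min_res/ALL)
ICC(2,k) FT_ALL: mean 0.835 +- 0.440, median 0.934 [excellent]
ICC(2,k) NF_ALL: mean 0.717 +- 1.151, median 0.935 [excellent]
ICC(2,k) FT_MM: mean 0.813 +- 0.280, median 0.880 [good]
ICC(2,k) NF_MM: mean 0.727 +- 0.815, median 0.881 [good]
```

Reading this: the generator injects fatigue effects on most waveform
parameters, and the two-way ANOVA detects a fatigue main effect for 74 of
the 78 feature × method comparisons — far above the ~4 expected by chance
— while interactions sit at chance level. Between-trial reliability is
good-to-excellent for most features (ALL higher than MM, since averaging
four trials is more stable than two), with the weakest values on ML-axis
features, whose trial-to-trial variance the generator deliberately makes
largest. The fourth script confirms the statistical layer is calibrated:

```
ICC(2,2) recovery: 0.6529 (expected 0.6667)
type-I error 7% (nominal 5%), power 95% (one-SD shift, n=16)
IC detection max error 1.77 ms over 2659 ICs
```

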