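import numpy as np
import pytest

from comgait import CohortSpec, RawTrial, iter_cohort, preprocess_trial


def make_trial(accel, rate, standing_s=2.0, warmup_s=300.0, rpe_log=None,
               subject="S01", label="MLSS1", cadence=180.0, ic_times=None):
    """Construct a RawTrial directly from an (n, 3) array (tests only)."""
    accel = np.asarray(accel, dtype=float)
    duration = len(accel) / rate - standing_s
    if rpe_log is None:
        rpe_log = [(float(m), min(11 + int(m // 5), 20))
                   for m in np.arange(5.0, duration / 60 + 1e-9, 5.0)]
        if not rpe_log:
            rpe_log = [(duration / 60, 11)]
    return RawTrial(subject_id=subject, trial_label=label, sampling_rate=rate,
                    time=np.arange(len(accel)) / rate - standing_s,
                    accel=accel, speed=3.35, duration=duration,
                    warmup_duration=warmup_s, standing_duration=standing_s,
                    rpe_log=rpe_log, true_ic_times=ic_times, cadence=cadence)


@pytest.fixture(scope="session")
def fast_spec():
    """Structurally complete but cheap cohort: short trials, 250 Hz."""
    return CohortSpec(n_subjects=2, sampling_rate=250.0, trial_duration=16.0,
                      trial_duration_sd=0.5, seed=42)


@pytest.fixture(scope="session")
def sim_trial(fast_spec):
    return next(iter_cohort(fast_spec))


@pytest.fixture(scope="session")
def stride_samples(sim_trial):
    nf, ft, _ = preprocess_trial(sim_trial)
    assert nf and ft
    return nf, ft
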