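"""ICC(2,k), repeated-measures ANOVAs, paired tests, the MLSS rule."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from statsmodels.stats.anova import AnovaRM

from comgait import (icc_2k, icc_category, identify_mlss, paired_rpe_test,
                     simulate_condition_means, simulate_icc_matrix,
                     trial_variable_anova, two_way_fatigue_trial_anova)
from comgait.reliability import rm_anova_one_way, rm_anova_two_way


def icc2k_bruteforce(mat):
    """First-principles ICC(2,k): explicit-loop sums of squares for the
    two-way subject x trial decomposition, then the Shrout-Fleiss
    average-measures absolute-agreement formula."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    grand = sum(mat[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssr = sum(k * (sum(mat[i]) / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (sum(mat[:, j]) / n - grand) ** 2 for j in range(k))
    sse = 0.0
    for i in range(n):
        for j in range(k):
            resid = mat[i, j] - sum(mat[i]) / k - sum(mat[:, j]) / n + grand
            sse += resid ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestIcc:
    def test_identical_trials_give_perfect_agreement(self):
        mat = np.column_stack([np.arange(6.0)] * 4)
        assert icc_2k(mat).icc == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            mat = rng.standard_normal((8, 4))
            assert icc_2k(mat).icc == pytest.approx(icc2k_bruteforce(mat),
                                                    abs=1e-9)

    def test_matches_pingouin_icc2k(self):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((10, 4)) + 2 * rng.standard_normal((10, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 4),
            "rater": np.tile(np.arange(4), 10),
            "score": mat.ravel()})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        # McGraw-Wong ICC(A,k) is the Shrout-Fleiss ICC(2,k)
        ref_val = ref.loc[ref["Type"] == "ICC(A,k)", "ICC"].iloc[0]
        assert icc_2k(mat).icc == pytest.approx(float(ref_val), abs=1e-6)

    def test_pure_noise_icc_near_zero(self):
        vals = [icc_2k(simulate_icc_matrix(200, 4, seed, sigma_subject=0.0,
                                           sigma_error=1.0)).icc
                for seed in range(10)]
        assert abs(np.mean(vals)) < 0.1
        assert np.max(np.abs(vals)) < 0.35     # single-draw sampling bound

    def test_variance_ratio_recovered(self):
        """sigma_s = sigma_e = 1, k = 2: expected ICC(2,k) =
        k*sigma_s^2/(k*sigma_s^2 + sigma_e^2) = 2/3, recovered at n = 500
        up to Monte-Carlo error (replicate mean)."""
        vals = [icc_2k(simulate_icc_matrix(500, 2, seed, sigma_subject=1.0,
                                           sigma_error=1.0)).icc
                for seed in range(10)]
        assert np.mean(vals) == pytest.approx(2.0 / 3.0, abs=0.05)

    def test_trial_offset_lowers_absolute_agreement(self):
        rng = np.random.default_rng(5)
        mat = np.column_stack([np.arange(10.0)] * 3) + 0.1 * rng.standard_normal((10, 3))
        shifted = mat.copy()
        shifted[:, 2] += 3.0
        assert icc_2k(shifted).icc < icc_2k(mat).icc

    def test_listwise_deletion_and_minimum_subjects(self):
        mat = np.column_stack([np.arange(6.0)] * 3)
        mat[0, 1] = np.nan
        res = icc_2k(mat)
        assert res.n_subjects == 5
        with pytest.raises(ValueError):
            icc_2k(np.array([[1.0, 2], [2, 3], [np.nan, 1]]))

    def test_category_bins(self):
        assert icc_category(0.49) == "poor"
        assert icc_category(0.5) == "moderate"
        assert icc_category(0.75) == "good"
        assert icc_category(0.9) == "excellent"
        assert icc_2k(np.column_stack([np.arange(5.0)] * 2)).category == "excellent"

    def test_monotone_decrease_with_trial_noise(self):
        iccs = []
        for i, sig_e in enumerate((0.2, 1.0, 3.0)):
            mat = simulate_icc_matrix(300, 4, 100 + i, sigma_subject=1.0,
                                      sigma_error=sig_e)
            iccs.append(icc_2k(mat).icc)
        assert iccs[0] > iccs[1] > iccs[2]
        assert iccs[0] > 0.9


def _long(cells):
    """(n, 2, t) array -> long df with windows NF/FT and trials T0..."""
    n, w, t = cells.shape
    rows = []
    for i in range(n):
        for wi, wname in enumerate(("NF", "FT")):
            for ti in range(t):
                rows.append((f"S{i:02d}", ["MLSS1", "MLSS2", "F", "S"][ti],
                             wname, cells[i, wi, ti]))
    return pd.DataFrame(rows, columns=["subject", "trial", "window", "value"])


class TestTwoWayAnova:
    def test_matches_statsmodels_on_random_data(self):
        rng = np.random.default_rng(0)
        for method, t in (("MM", 2), ("ALL", 4)):
            cells = rng.standard_normal((8, 2, t))
            df = _long(np.concatenate(
                [cells, rng.standard_normal((8, 2, 4 - t))], axis=2))
            mine = {r.effect: r for r in two_way_fatigue_trial_anova(df, method)}
            sub = df[df["trial"].isin(["MLSS1", "MLSS2"])] if method == "MM" else df
            ref = AnovaRM(sub, depvar="value", subject="subject",
                          within=["window", "trial"]).fit().anova_table
            for key, eff in (("window", "fatigue_state"), ("trial", "trial"),
                             ("window:trial", "interaction")):
                assert mine[eff].F == pytest.approx(ref.loc[key, "F Value"],
                                                    abs=1e-9)
                assert mine[eff].p == pytest.approx(ref.loc[key, "Pr > F"],
                                                    abs=1e-9)

    def test_constructed_fatigue_shift_detected_with_sign(self):
        n = 8
        base = np.arange(n, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        cells = base.copy()
        cells[:, 1, :] += 2.0          # +c in FT only, identical across trials
        res = {r.effect: r for r in two_way_fatigue_trial_anova(_long(
            np.concatenate([cells, cells], axis=2)[:, :, :4]), "MM")}
        assert res["fatigue_state"].p < 0.05
        assert res["fatigue_state"].direction == "+"
        assert res["trial"].p > 0.05
        assert res["interaction"].p > 0.05

    def test_type_i_error_near_nominal(self):
        """Null generator: fatigue effect significant in ~5% of replicates
        (binomial tolerance 1-11% over 100 runs)."""
        hits = 0
        for seed in range(100):
            df = simulate_condition_means(16, seed, sigma_subject=1.0,
                                          sigma_trial=0.3, sigma_error=1.0,
                                          fatigue_shift=0.0)
            res = {r.effect: r for r in two_way_fatigue_trial_anova(df, "MM")}
            hits += res["fatigue_state"].p < 0.05
        assert 1 <= hits <= 11

    def test_power_for_one_sd_fatigue_shift(self):
        """A fatigue shift equal to one within-subject SD is detected in
        >= 80% of replicates at n = 16."""
        hits = 0
        for seed in range(100):
            df = simulate_condition_means(16, 10_000 + seed, sigma_subject=1.0,
                                          sigma_trial=0.3, sigma_error=1.0,
                                          fatigue_shift=1.0)
            res = {r.effect: r for r in two_way_fatigue_trial_anova(df, "MM")}
            hits += res["fatigue_state"].p < 0.05
        assert hits >= 80

    def test_invariance_to_constant_shift_and_relabeling(self):
        rng = np.random.default_rng(3)
        cells = rng.standard_normal((8, 2, 4))
        df = _long(cells)
        base = two_way_fatigue_trial_anova(df, "ALL")
        shifted = df.copy()
        shifted["value"] += 100.0
        relabeled = df.copy()
        relabeled["subject"] = relabeled["subject"].map(
            lambda s: f"Z{int(s[1:]) ^ 5:02d}")
        for other in (shifted, relabeled):
            got = two_way_fatigue_trial_anova(other, "ALL")
            for r0, r1 in zip(base, got):
                assert r1.p == pytest.approx(r0.p, abs=1e-9)

    def test_unbalanced_subject_dropped_then_error_if_none_left(self):
        rng = np.random.default_rng(4)
        df = _long(rng.standard_normal((4, 2, 4)))
        df = df[~((df.subject == "S00") & (df.trial == "F"))]
        res = two_way_fatigue_trial_anova(df, "ALL")
        assert res[0].p >= 0          # ran on the 3 complete subjects
        tiny = df[df.subject == "S00"]
        with pytest.raises(ValueError):
            two_way_fatigue_trial_anova(tiny, "ALL")


class TestOneWayAnova:
    def test_identical_trials_give_null_result(self):
        df = pd.DataFrame({"subject": list("abcd") * 4,
                           "trial": np.repeat(["MLSS1", "MLSS2", "F", "S"], 4),
                           "value": list(range(4)) * 4})
        res = trial_variable_anova(df)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_shifted_trial_detected(self):
        rng = np.random.default_rng(6)
        rows = []
        for s in range(8):
            for t in ("MLSS1", "MLSS2", "F", "S"):
                v = rng.standard_normal() * 0.1 + (5.0 if t == "F" else 0.0)
                rows.append((f"S{s}", t, v))
        df = pd.DataFrame(rows, columns=["subject", "trial", "value"])
        assert trial_variable_anova(df).p < 1e-6

    def test_null_rejection_rate_within_binomial_band(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(20_000 + seed)
            rows = [(f"S{s}", t, rng.standard_normal())
                    for s in range(12) for t in ("MLSS1", "MLSS2", "F", "S")]
            df = pd.DataFrame(rows, columns=["subject", "trial", "value"])
            hits += trial_variable_anova(df).p < 0.05
        assert 1 <= hits <= 11

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        rows = [(f"S{s}", t, rng.standard_normal())
                for s in range(6) for t in ("MLSS1", "MLSS2", "F", "S")]
        df = pd.DataFrame(rows, columns=["subject", "trial", "value"])
        mine = trial_variable_anova(df)
        ref = AnovaRM(df, depvar="value", subject="subject",
                      within=["trial"]).fit().anova_table.loc["trial"]
        assert mine.F == pytest.approx(ref["F Value"], abs=1e-9)
        assert mine.p == pytest.approx(ref["Pr > F"], abs=1e-9)


class TestPairedRpe:
    def test_identical_vectors(self):
        res = paired_rpe_test([11, 12, 13, 14], [11, 12, 13, 14])
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_hand_computed_t(self):
        # differences {1,2,3,4}: t = 2.5 / (1.2910/2) = 3.873, df 3
        res = paired_rpe_test([10, 10, 10, 10], [11, 12, 13, 14])
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert res.df == 3
        assert not res.degenerate

    def test_power_at_protocol_scale_effect(self):
        """Delta RPE ~ +4 with SD 2 at n = 16 is detected essentially
        always (paired t, alpha = 0.05)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            nf = rng.normal(11.5, 1.7, 16)
            ft = nf + rng.normal(4.0, 2.0, 16)
            hits += paired_rpe_test(nf, ft).p < 0.05
        assert hits >= 95

    def test_validation(self):
        with pytest.raises(ValueError):
            paired_rpe_test([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_rpe_test([1, 2], [1, 2])


class TestMlssRule:
    @pytest.mark.parametrize("l10,l30,done,expect", [
        (3.0, 3.8, True, "steady"),        # delta 0.8 < 1
        (3.0, 4.0, True, "not_steady"),    # delta exactly 1 fails '< 1'
        (2.5, 3.0, False, "not_steady"),   # did not complete 30 min
    ])
    def test_rule(self, l10, l30, done, expect):
        assert identify_mlss(l10, l30, done) == expect

    def test_missing_or_negative_rejected(self):
        with pytest.raises(ValueError):
            identify_mlss(float("nan"), 3.0, True)
        with pytest.raises(ValueError):
            identify_mlss(-0.1, 3.0, True)


class TestDegenerateAnovaConventions:
    def test_all_constant_data(self):
        cells = np.ones((5, 2, 2))
        res = rm_anova_two_way(cells)
        for f, _, p in res.values():
            assert f == 0.0 and p == 1.0

    def test_perfectly_replicated_effect_is_infinitely_significant(self):
        f, _, p = rm_anova_one_way(np.array([[0.0, 1.0]] * 5))
        assert np.isinf(f) and p == 0.0
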