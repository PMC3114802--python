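"""The detection statistic: summaries, line fits, residuals, FDR, calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oracles import detection_chain_oracle, lms_bruteforce
from qanet._errors import ParameterError, StructuralError
from qanet.preprocess import normalize_set
from qanet.responders import (
    averaged_line,
    by_correct,
    classify_responders,
    fit_lms,
    fit_ols,
    gene_summaries,
    gene_summary,
    identify_experiment,
    paired_t_screen,
    standardized_residuals,
    summary_counts,
)
from qanet.synth import QA_CLASSES, TruthConfig, simulate_experiment_set


class TestGeneSummary:
    @pytest.mark.parametrize("profile,expected", [
        ([3.0] * 8, (3.0, 3.0)),
        ([0, 7, 7, 7, 7, 7, 7, 7], (0.0, 7.0)),
        ([1, 2, 3, 4, 5, 6, 7, 8], (1.0, 5.0)),
    ])
    def test_examples(self, profile, expected):
        assert gene_summary(profile) == pytest.approx(expected)

    def test_wrong_length_rejected(self):
        with pytest.raises(ParameterError):
            gene_summary([1.0, 2.0])

    def test_vectorized_matches_scalar(self, rng):
        z = rng.normal(size=(8, 20))
        z0, zavg = gene_summaries(z)
        for k in range(20):
            assert (z0[k], zavg[k]) == pytest.approx(gene_summary(z[:, k]))


class TestFitOls:
    def test_collinear_points_recovered(self):
        x = np.arange(5.0)
        fit = fit_ols(x, 2 * x + 1)
        assert (fit.beta0, fit.beta1) == pytest.approx((1.0, 2.0))

    def test_outlier_example_closed_form(self):
        fit = fit_ols([0, 1, 2, 3, 4], [0, 1, 2, 3, 10])
        assert fit.beta1 == pytest.approx(2.2)
        assert fit.beta0 == pytest.approx(-1.2)

    def test_intercept_equivariance_under_y_shift(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a = fit_ols(x, y)
        b = fit_ols(x, y + 5.5)
        assert b.beta1 == pytest.approx(a.beta1)
        assert b.beta0 == pytest.approx(a.beta0 + 5.5)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ParameterError):
            fit_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFitLms:
    def test_majority_on_line_recovered_exactly(self, rng):
        x = np.arange(9.0)
        y = x.copy()
        y[7:] = [40.0, -31.0]  # 7 of 9 on y = x
        fit = fit_lms(x, y, seed=0)
        assert (fit.beta0, fit.beta1) == pytest.approx((0.0, 1.0), abs=1e-12)
        assert fit.objective == pytest.approx(0.0, abs=1e-20)

    def test_outlier_example_ignores_leverage_point(self):
        fit = fit_lms([0, 1, 2, 3, 4], [0, 1, 2, 3, 10], seed=0)
        assert (fit.beta0, fit.beta1) == pytest.approx((0.0, 1.0))
        assert fit.objective == pytest.approx(0.0)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(4, 13))
            x = rng.normal(size=n)
            y = 0.7 * x + rng.normal(size=n)
            fit = fit_lms(x, y, seed=int(trial))
            b0, b1, obj = lms_bruteforce(x, y)
            assert fit.beta0 == pytest.approx(b0, abs=1e-10)
            assert fit.beta1 == pytest.approx(b1, abs=1e-10)
            assert fit.objective == pytest.approx(obj, abs=1e-10)

    def test_objective_never_exceeds_ols_median_squared_residual(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + x
            fit = fit_lms(x, y, seed=1)
            ols = fit_ols(x, y)
            ols_obj = np.median((y - ols.predict(x)) ** 2)
            assert fit.objective <= ols_obj + 1e-12

    def test_resampling_branch_is_seed_deterministic(self, rng):
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        a = fit_lms(x, y, seed=9, n_exact=100)
        b = fit_lms(x, y, seed=9, n_exact=100)
        assert (a.beta0, a.beta1) == (b.beta0, b.beta1)

    def test_identical_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_lms([1.0] * 5, [2.0] * 5)


class TestStandardizedResiduals:
    def test_point_on_averaged_line_has_p_half(self, rng):
        x = np.linspace(0, 1, 10)
        y = 2 * x + 1 + rng.normal(0, 0.1, 10)
        lo = fit_ols(x, y)
        ll = fit_lms(x, y, seed=0)
        line = averaged_line(lo, ll)
        x2 = np.append(x, 0.5)
        y2 = np.append(y, line.predict(0.5))
        res = standardized_residuals(x2, y2, lo, ll)
        assert res.standardized[-1] == pytest.approx(0.0, abs=1e-12)
        assert res.p_upper[-1] == pytest.approx(0.5)

    def test_p_value_at_critical_residual(self):
        from scipy.stats import norm
        assert norm.sf(1.6449) == pytest.approx(0.05, abs=1e-4)

    def test_scale_calibration_on_normal_residuals(self, rng):
        # p75(|N(0,1)|) = 1.1503... ~ 1.15, so s -> 1 for standard normal
        # residuals around a known line
        x = rng.normal(size=100_000)
        y = x + rng.normal(size=100_000)
        line = type("L", (), {})
        lo = fit_ols(x, y)
        ll = fit_lms(x, y, seed=0)
        res = standardized_residuals(x, y, lo, ll)
        assert res.scale_s == pytest.approx(1.0, abs=0.02)

    def test_zero_scale_handled_without_error(self):
        # >=75% of points exactly on the line: responders get infinite r
        x = np.arange(20.0)
        y = x.copy()
        y[-2:] += 9.0
        lo = fit_ols(x, x)
        ll = fit_lms(x, x, seed=0)
        res = standardized_residuals(x, y, lo, ll)
        assert res.degenerate_scale
        assert np.all(np.isposinf(res.standardized[-2:]))
        assert res.p_upper[-1] == 0.0
        assert np.all(res.standardized[:-2] == 0.0)


class TestByCorrect:
    def test_all_ones_no_rejections(self):
        assert not by_correct(np.ones(10), 0.10).any()

    def test_step_up_worked_example(self):
        rej = by_correct([0.001, 0.01, 0.02, 0.9], alpha=0.10)
        assert rej.tolist() == [True, True, True, False]

    def test_empty_input(self):
        assert by_correct([], 0.1).size == 0

    def test_alpha_zero_rejects_nothing(self):
        assert not by_correct([0.0, 0.5], alpha=0.0).any()

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 60),
           alpha=st.floats(0.01, 0.4))
    def test_matches_statsmodels_and_is_subset_of_bh(self, seed, m, alpha):
        p = np.random.default_rng(seed).uniform(size=m) ** 2
        ours = by_correct(p, alpha)
        ref = multipletests(p, alpha=alpha, method="fdr_by")[0]
        assert np.array_equal(ours, ref)
        bh = multipletests(p, alpha=alpha, method="fdr_bh")[0]
        assert np.all(bh[ours])  # BY rejections are a subset of BH's

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_alpha_and_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=30)
        # rejection set grows with alpha
        small = by_correct(p, 0.05)
        large = by_correct(p, 0.20)
        assert np.all(large[small])
        # lowering any p never removes rejections (step-up monotonicity)
        lowered = p.copy()
        lowered[rng.integers(30)] /= 10
        before = by_correct(p, 0.10)
        after = by_correct(lowered, 0.10)
        assert np.all(after[before])


class TestIdentifyAndClassify:
    def test_noiseless_planted_responders_fully_recovered(self, small_layout):
        # the screening experiments (qa-1F mutant, control) are null here:
        # with zero noise a planted control responder tilts the control
        # regression deterministically and the robust scale collapses, so
        # extreme-abundance features would be spuriously flagged -- an
        # artifact specific to noise-free data
        cfg = TruthConfig(n_qa_immediate=8, n_qa_gradual=3, n_qa_delayed=3,
                          n_qa_concave=2, n_leaky=2, n_starvation=8, n_both=2,
                          n_down_in_control=0, n_qa1f_spurious=0)
        chipset, truth = simulate_experiment_set(
            small_layout, cfg, noise_sd_log2=0.0, seed=31)
        norm = normalize_set(chipset, small_layout)
        calls = [identify_experiment(norm.z[i], alpha=0.10, seed=1)
                 for i in range(4)]
        cs = classify_responders(*calls, feature_ids=small_layout.feature_ids)
        found = set(cs.responsive_genes(small_layout))
        planted = {g for g, c in truth.class_of_gene.items()
                   if c in QA_CLASSES}
        assert found == planted

    def test_chain_matches_independent_reimplementation(self, small_layout,
                                                        small_truth_config):
        chipset, _ = simulate_experiment_set(
            small_layout, small_truth_config, noise_sd_log2=0.5, seed=77)
        norm = normalize_set(chipset, small_layout)
        for i in range(4):
            calls = identify_experiment(norm.z[i], alpha=0.10, seed=5)
            oracle_up = detection_chain_oracle(
                norm.z[i], 0.10,
                (calls.line_lms.beta0, calls.line_lms.beta1))
            assert np.array_equal(calls.up, oracle_up)

    def test_chain_invariant_under_common_z_shift(self, small_layout,
                                                  small_truth_config):
        chipset, _ = simulate_experiment_set(
            small_layout, small_truth_config, noise_sd_log2=0.4, seed=13)
        norm = normalize_set(chipset, small_layout)
        a = identify_experiment(norm.z[0], alpha=0.10, seed=2)
        b = identify_experiment(norm.z[0] + 3.7, alpha=0.10, seed=2)
        assert np.array_equal(a.up, b.up)
        assert np.array_equal(a.down, b.down)

    @pytest.mark.parametrize("flags,expected", [
        ((True, False, False, False), "qa_responsive"),
        ((True, True, False, False), "qa_and_starvation"),
        ((True, False, True, False), "rejected_by_qa1F"),
        ((True, False, False, True), "rejected_by_control"),
        ((False, False, False, False), "not_responsive"),
    ])
    def test_classification_rules(self, flags, expected):
        import dataclasses
        from qanet.responders import ExperimentCalls, LineFit

        def mk(up):
            n = 1
            return ExperimentCalls(
                np.array([up]), np.array([False]), np.ones(n), np.ones(n),
                np.zeros(n), LineFit(0, 1, "OLS"), LineFit(0, 1, "LMS"), 0.1)

        cs = classify_responders(mk(flags[0]), mk(flags[1]), mk(flags[2]),
                                 mk(flags[3]), ["f1"])
        assert cs.final_class[0] == expected

    def test_feature_mismatch_raises(self):
        from qanet.responders import ExperimentCalls, LineFit
        mk = lambda n: ExperimentCalls(
            np.zeros(n, bool), np.zeros(n, bool), np.ones(n), np.ones(n),
            np.zeros(n), LineFit(0, 1, "OLS"), LineFit(0, 1, "LMS"), 0.1)
        with pytest.raises(StructuralError):
            classify_responders(mk(2), mk(3), mk(2), mk(2), ["a", "b"])

    def test_summary_counts_shape(self, small_layout, small_truth_config):
        chipset, _ = simulate_experiment_set(
            small_layout, small_truth_config, noise_sd_log2=0.4, seed=3)
        norm = normalize_set(chipset, small_layout)
        counts = summary_counts({"qa": norm.z[0]}, alpha=0.10, seed=0)
        entry = counts["qa"]
        assert set(entry) == {"OLS", "LMS", "averaged"}
        for method in entry.values():
            assert method["corrected"] <= method["naive"]


class TestPairedTScreen:
    def test_identical_profiles_not_significant(self, rng):
        prof = rng.normal(size=(8, 5))
        t, sig, zero = paired_t_screen(prof, prof)
        assert np.all(t == 0) and not sig.any()

    def test_critical_value_is_t7_two_sided_005(self):
        from scipy.stats import t as tdist
        assert tdist.ppf(0.975, df=7) == pytest.approx(2.365, abs=5e-4)

    def test_textbook_hand_computation(self):
        d = np.array([1, 1, 1, 1, 1, 1, 1, 2.0])
        exp = d[:, None]
        ctl = np.zeros_like(exp)
        t, sig, zero = paired_t_screen(exp, ctl)
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(8))
        assert t[0] == pytest.approx(expected)
        assert sig[0] == (expected > 2.365)

    def test_zero_variance_nonzero_mean_flagged_significant(self):
        exp = np.ones((8, 1))
        ctl = np.zeros((8, 1))
        t, sig, zero = paired_t_screen(exp, ctl)
        assert zero[0] and np.isposinf(t[0]) and sig[0]
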