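"""Reliability statistics: correlations, corrections, tests, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from discountfit import (Dataset, PopulationConfig, ScheduleConfig,
                         bootstrap_test, compare_dependent_correlations,
                         corrected_rank_correlation, correlation_ceiling,
                         correlation_with_ci, cross_task_regression,
                         gap_variance_mixed_model, simulate_cohort)
from discountfit import test_retest_summary as split_half_summary
from discountfit.reliability import CeilingSimConfig

from conftest import small_schedules


class TestCorrelationCI:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlation_with_ci(x, x)["r"] == pytest.approx(1.0)
        assert correlation_with_ci(x, -x)["r"] == pytest.approx(-1.0)
        assert correlation_with_ci(x, x ** 3, "spearman", n_boot=200)["r"] == \
            pytest.approx(1.0)

    def test_null_ci_covers_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        res = correlation_with_ci(x, y)
        assert abs(res["r"]) < 0.1
        assert res["ci95"][0] < 0 < res["ci95"][1]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_with_ci(np.ones(10), np.arange(10.0))

    def test_fisher_interval_tightens_with_n(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(400)
        x = z + 0.5 * rng.standard_normal(400)
        small = correlation_with_ci(x[:40], z[:40])
        large = correlation_with_ci(x, z)
        assert (large["ci95"][1] - large["ci95"][0]) < \
            (small["ci95"][1] - small["ci95"][0])


class TestAttenuationCorrection:
    def test_normalization_identities(self):
        assert corrected_rank_correlation(0.9, 0.9)["corrected_r"] == 1.0
        assert corrected_rank_correlation(0.0, 0.95)["corrected_r"] == 0.0

    def test_cap_and_flag_above_ceiling(self):
        res = corrected_rank_correlation(0.97, 0.9)
        assert res["corrected_r"] == 1.0 and res["capped"]

    def test_nonpositive_ceiling_rejected(self):
        with pytest.raises(ValueError):
            corrected_rank_correlation(0.5, 0.0)

    def test_ceiling_rises_with_trial_count(self):
        # estimation noise shrinks with trials, so the attainable rank
        # correlation must grow toward 1
        def ceiling(n_trials):
            cfg = CeilingSimConfig(
                schedule_a=ScheduleConfig.for_task("SV", n_trials=n_trials,
                                                   sessions=(1,)),
                schedule_b=ScheduleConfig.for_task("SV", n_trials=n_trials,
                                                   sessions=(1,)),
                n_subjects=25, n_replicates=8)
            return correlation_ceiling(cfg, seed=0)["ceiling"]

        low, high = ceiling(40), ceiling(640)
        assert high > low
        assert high > 0.93

    def test_correction_monotone_in_observed(self):
        c = 0.92
        vals = [corrected_rank_correlation(r, c)["corrected_r"]
                for r in (0.2, 0.5, 0.8)]
        assert vals == sorted(vals)


class TestDependentCorrelations:
    def test_null_identity(self):
        res = compare_dependent_correlations(0.5, 0.5, 0.3, 50)
        assert res["steiger_z"] == pytest.approx(0.0, abs=1e-12)
        assert res["steiger_p"] == pytest.approx(1.0)
        assert res["williams_p"] == pytest.approx(1.0)

    def test_study_contrast_is_significant(self):
        # the short-task pair correlates more strongly than the
        # cross-horizon pair at n = 63
        res = compare_dependent_correlations(0.79, 0.61, 0.40, 63)
        assert res["steiger_p"] < 0.05 and res["williams_p"] < 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(1.0, 0.5, 0.3, 30)

    def test_agreement_with_permutation_oracle(self):
        # swap the identities of variables 2 and 3 at random: under the
        # null r12 = r13 this is exchangeable, giving an exact reference
        # distribution for the observed difference
        rng = np.random.default_rng(4)
        n = 20
        R = np.array([[1, 0.6, 0.45], [0.6, 1, 0.3], [0.45, 0.3, 1]])
        X = rng.standard_normal((n, 3)) @ np.linalg.cholesky(R).T
        r12 = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        r13 = np.corrcoef(X[:, 0], X[:, 2])[0, 1]
        r23 = np.corrcoef(X[:, 1], X[:, 2])[0, 1]
        analytic = compare_dependent_correlations(r12, r13, r23, n)
        obs = r12 - r13
        null = []
        for _ in range(4000):
            swap = rng.random(n) < 0.5
            Y = X.copy()
            Y[swap, 1], Y[swap, 2] = X[swap, 2], X[swap, 1]
            null.append(np.corrcoef(Y[:, 0], Y[:, 1])[0, 1]
                        - np.corrcoef(Y[:, 0], Y[:, 2])[0, 1])
        p_perm = np.mean(np.abs(null) >= abs(obs))
        mc_se = np.sqrt(p_perm * (1 - p_perm) / 4000)
        assert abs(analytic["williams_p"] - p_perm) < 4 * mc_se + 0.06


class TestBootstrap:
    def test_large_shift_rejects(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 40)
        assert bootstrap_test(a, seed=1)["p"] < 1e-3

    def test_identical_paired_groups_accept(self):
        a = np.arange(20.0)
        res = bootstrap_test(a, a, paired=True, seed=0)
        assert res["p"] > 0.99 and res["degenerate"]

    def test_seed_deterministic(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 25), rng.normal(0.3, 1, 25)
        r1 = bootstrap_test(a, b, seed=7)
        r2 = bootstrap_test(a, b, seed=7)
        assert r1["p"] == r2["p"]

    def test_two_sample_unpaired_null_behaves(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
        res = bootstrap_test(a, b, n_boot=3000, seed=2)
        assert res["p"] > 0.05

    @pytest.mark.parametrize("statistic", ["mean", "median", "variance"])
    def test_statistics_supported(self, statistic):
        rng = np.random.default_rng(1)
        res = bootstrap_test(rng.normal(2, 1, 30), statistic=statistic,
                             n_boot=500, seed=0)
        assert 0 <= res["p"] <= 1


class TestCrossTaskRegression:
    def test_exact_linear_response(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"SV": rng.normal(-3.5, 1, 40),
                            "LV": rng.normal(-4, 1, 40)})
        tab["NV"] = 1.3 * tab["SV"] - 0.2 * tab["LV"] + 0.5
        res = cross_task_regression(tab, "NV", ["SV", "LV"])
        assert res.r2 == pytest.approx(1.0)
        assert res.params["SV"] == pytest.approx(1.3, abs=1e-8)

    def test_coefficient_recovery_with_noise(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"SV": rng.normal(-3.5, 1, 200),
                            "LV": rng.normal(-4, 1, 200)})
        tab["NV"] = 1.3 * tab["SV"] + 0.0 * tab["LV"] + rng.normal(0, 0.5, 200)
        res = cross_task_regression(tab, "NV", ["SV", "LV"])
        assert abs(res.params["SV"] - 1.3) < 3 * res.bse["SV"]
        assert abs(res.params["LV"]) < 3 * res.bse["LV"]

    def test_null_extra_factors_rarely_significant(self):
        rng = np.random.default_rng(2)
        rejections = 0
        trials = 120
        for i in range(trials):
            tab = pd.DataFrame({"SV": rng.normal(0, 1, 60)})
            tab["NV"] = tab["SV"] + rng.normal(0, 0.5, 60)
            extra = pd.DataFrame({"anchor": rng.normal(0, 1, 60)})
            res = cross_task_regression(tab, "NV", ["SV"], extra_factors=extra)
            rejections += res.lr_tests["anchor"]["p"] < 0.05
        assert rejections / trials < 0.12

    def test_collinear_design_rejected(self):
        tab = pd.DataFrame({"SV": np.arange(10.0), "LV": 2 * np.arange(10.0)})
        tab["NV"] = tab["SV"]
        with pytest.raises(ValueError, match="rank"):
            cross_task_regression(tab, "NV", ["SV", "LV"])


class TestGapVarianceModel:
    def _long_table(self, n, days_effect, verbal_effect, subj_sd, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            b = rng.normal(0, subj_sd)
            for task in ("NV", "SV", "LV"):
                days = 1.0 if task == "LV" else 0.0
                verbal = 0.0 if task == "NV" else 1.0
                rows.append({"subjid": f"s{i}", "task": task,
                             "logk": -3.5 + days_effect * days
                             + verbal_effect * verbal + b + rng.normal(0, 0.4)})
        return pd.DataFrame(rows)

    def test_recovers_days_effect_pattern(self):
        tab = self._long_table(60, days_effect=-0.52, verbal_effect=0.0,
                               subj_sd=0.8, seed=0)
        res = gap_variance_mixed_model(tab)
        assert res.lr_tests["days"]["p"] < 0.05
        assert res.lr_tests["verbal"]["p"] > 0.05
        assert abs(res.params["days"] - (-0.52)) < 3 * res.bse["days"]

    def test_null_effects_calibrated(self):
        rejections = {"days": 0, "verbal": 0}
        trials = 40
        for i in range(trials):
            tab = self._long_table(40, 0.0, 0.0, 0.6, seed=100 + i)
            res = gap_variance_mixed_model(tab)
            for f in rejections:
                rejections[f] += res.lr_tests[f]["p"] < 0.05
        for f, c in rejections.items():
            assert c / trials < 0.18

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.api as sm

        tab = self._long_table(50, -0.4, 0.2, subj_sd=0.0, seed=3)
        res = gap_variance_mixed_model(tab)
        X = sm.add_constant(pd.DataFrame({
            "days": (tab.task == "LV").astype(float),
            "verbal": (tab.task != "NV").astype(float)}))
        ols = sm.OLS(tab.logk, X).fit()
        assert res.params["days"] == pytest.approx(ols.params["days"], abs=0.02)
        assert res.params["verbal"] == pytest.approx(ols.params["verbal"], abs=0.02)

    def test_single_task_subjects_rejected(self):
        tab = pd.DataFrame({"subjid": ["a", "b"], "task": ["SV", "SV"],
                            "logk": [-3, -4]})
        with pytest.raises(ValueError):
            gap_variance_mixed_model(tab)


class TestTestRetest:
    def test_stationary_agent_halves_agree(self, medium_cohort):
        # 60-trial tasks leave ~30 trials per half, so binomial noise
        # bounds the attainable split-half correlation well below 1
        dataset, _, _ = medium_cohort
        res = split_half_summary(dataset, split="half_block")
        assert res["pearson_r"] > 0.6
        assert res["wilcoxon_p"] > 0.01

    def test_unknown_split_rejected(self, small_cohort):
        dataset, _, _ = small_cohort
        with pytest.raises(ValueError):
            split_half_summary(dataset, split="thirds")
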