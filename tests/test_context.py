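"""Temporal-context analyses: utility differences, adaptation GLMM,
shift/scale evidence ratios, unit-shift predictions."""

import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest

from discountfit import (Dataset, HierarchicalConfig, PopulationConfig,
                         adaptation_glmm, delta_utility, fit_hierarchical,
                         shift_scale_report, simulate_cohort,
                         unit_shift_prediction)
from discountfit.context import fit_logistic_glmm, _design

from conftest import small_schedules


def _fits_frame(pairs):
    return pd.DataFrame([{"subjid": s, "task": t, "logk": v}
                         for (s, t), v in pairs.items()])


def simulate_glmm_records(seed, n_subj=10, n_tr=50, lv_early=0.0,
                          beta_du=1.0, re_sd=(0.5, 0.3)):
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subj):
        b0 = rng.normal(0, re_sd[0])
        b1 = rng.normal(0, re_sd[1])
        for task in ("SV", "LV"):
            du = rng.normal(0, 1.5, n_tr)
            early = (np.arange(n_tr) < 4).astype(float)
            lv = float(task == "LV")
            x = (0.2 + b0) + (beta_du + b1 + 0.2 * lv) * du - 0.3 * lv \
                + lv_early * lv * early
            y = rng.random(n_tr) < 1 / (1 + np.exp(-x))
            frames.append(pd.DataFrame({
                "subjid": f"s{s:02d}", "task": task,
                "trial_index": np.arange(1, n_tr + 1),
                "early": early.astype(bool), "delta_u": du, "chose_later": y}))
    return pd.concat(frames, ignore_index=True)


class TestDeltaUtility:
    def test_matches_brute_force(self, small_cohort):
        dataset, agents, _ = small_cohort
        fits = _fits_frame({(a.subject_id, t): a.logk[t]
                            for a in agents for t in ("SV", "LV")})
        rec = delta_utility(dataset, fits)
        merged = rec.merge(dataset.trials, left_on=["subjid", "task", "trial_index"],
                           right_on=["subjid", "task", "trial"])
        k = np.exp(merged.merge(fits, on=["subjid", "task"])["logk"])
        expect = merged.later_mag / (1 + k * merged.later_delay) - merged.sooner_mag
        assert np.abs(rec["delta_u"].to_numpy() - expect.to_numpy()).max() < 1e-12

    def test_indifference_point_is_zero(self):
        # V/(1+kT) = sooner exactly: V=8, sooner=4, kT=1
        trials = pd.DataFrame([dict(subjid="s1", task="SV", session=1, block=1,
                                    trial=1, sooner_mag=4.0, later_mag=8.0,
                                    later_delay=10.0, delay_unit="second",
                                    chose_later=True)])
        fits = _fits_frame({("s1", "SV"): np.log(1 / 10.0)})
        rec = delta_utility(Dataset(trials=trials), fits, tasks=("SV",))
        assert rec["delta_u"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_later_magnitude(self, small_cohort):
        dataset, agents, _ = small_cohort
        fits = _fits_frame({(a.subject_id, t): a.logk[t]
                            for a in agents for t in ("SV", "LV")})
        rec = delta_utility(dataset, fits)
        merged = rec.merge(dataset.trials, left_on=["subjid", "task", "trial_index"],
                           right_on=["subjid", "task", "trial"])
        one = merged[(merged.subjid == merged.subjid.iloc[0]) &
                     (merged.task == "SV")]
        for delay, grp in one.groupby("later_delay"):
            srt = grp.sort_values("later_mag")
            assert srt["delta_u"].is_monotonic_increasing

    def test_missing_fit_skips_subject(self, small_cohort):
        dataset, agents, _ = small_cohort
        fits = _fits_frame({(a.subject_id, t): a.logk[t]
                            for a in agents[1:] for t in ("SV", "LV")})
        rec = delta_utility(dataset, fits)
        assert agents[0].subject_id not in set(rec.subjid)
        assert rec.attrs["skipped"] == [agents[0].subject_id]

    def test_pure_function_of_inputs(self, small_cohort):
        dataset, agents, _ = small_cohort
        fits = _fits_frame({(a.subject_id, t): a.logk[t]
                            for a in agents for t in ("SV", "LV")})
        a = delta_utility(dataset, fits)
        b = delta_utility(dataset, fits)
        pd.testing.assert_frame_equal(a, b)


class TestAdaptationGlmm:
    def test_recovers_interaction(self):
        rec = simulate_glmm_records(seed=0, n_subj=25, n_tr=60, lv_early=0.86)
        res = adaptation_glmm(rec)
        beta = res["full"].beta["lv:early"]
        se = res["full"].beta_se["lv:early"]
        assert abs(beta - 0.86) < 3 * se
        assert res["p"] < 0.05

    def test_matches_lme4_oracle(self, tmp_path):
        # lme4::glmer (Laplace) is the independent reference
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        rec = simulate_glmm_records(seed=5, n_subj=15, n_tr=60, lv_early=0.8)
        csv = tmp_path / "rec.csv"
        out = rec.copy()
        out["chose_later"] = out["chose_later"].astype(int)
        out["early"] = out["early"].astype(int)
        out.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$lv <- as.numeric(d$task == "LV")
full <- glmer(chose_later ~ delta_u + lv:delta_u + lv*early + (1 + delta_u | subjid),
              data=d, family=binomial, control=glmerControl(optimizer="bobyqa"))
red <- glmer(chose_later ~ delta_u + lv:delta_u + lv + (1 + delta_u | subjid),
             data=d, family=binomial, control=glmerControl(optimizer="bobyqa"))
cat(fixef(full)["lv:early"], as.numeric(logLik(full)), as.numeric(logLik(red)), sep=",")
""")
        r = subprocess.run(["Rscript", str(script)], capture_output=True,
                           text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        r_beta, r_llf, r_llr = map(float, r.stdout.strip().split(","))
        res = adaptation_glmm(rec)
        assert res["full"].beta["lv:early"] == pytest.approx(r_beta, abs=0.02)
        assert res["full"].loglik == pytest.approx(r_llf, abs=0.1)
        assert res["reduced"].loglik == pytest.approx(r_llr, abs=0.1)

    def test_zero_variance_matches_plain_logistic(self):
        import statsmodels.api as sm

        rec = simulate_glmm_records(seed=2, n_subj=12, n_tr=60, lv_early=0.5,
                                    re_sd=(0.0, 0.0))
        res = adaptation_glmm(rec)
        X, names = _design(rec, full=True)
        glm = sm.GLM(rec.chose_later.astype(float), X,
                     family=sm.families.Binomial()).fit()
        for i, name in enumerate(names):
            assert res["full"].beta[name] == pytest.approx(glm.params.iloc[i],
                                                           abs=0.06)

    def test_lr_invariant_to_subject_relabeling(self):
        rec = simulate_glmm_records(seed=3, n_subj=8, n_tr=40, lv_early=0.4)
        relabeled = rec.copy()
        mapping = {f"s{i:02d}": f"x{(i * 7) % 8}" for i in range(8)}
        relabeled["subjid"] = relabeled["subjid"].map(mapping)
        a = adaptation_glmm(rec, compute_se=False)
        b = adaptation_glmm(relabeled, compute_se=False)
        assert a["lr_chi2"] == pytest.approx(b["lr_chi2"], abs=1e-3)

    def test_no_adaptation_favors_reduced_model_by_aic(self):
        worse = 0
        for i in range(10):
            rec = simulate_glmm_records(seed=50 + i, n_subj=8, n_tr=40)
            res = adaptation_glmm(rec, compute_se=False)
            worse += res["full"].aic > res["reduced"].aic
        assert worse >= 7

    def test_requires_early_and_late_in_both_tasks(self):
        rec = simulate_glmm_records(seed=1)
        with pytest.raises(ValueError):
            adaptation_glmm(rec[~rec.early])


class TestShiftScale:
    @pytest.fixture(scope="class")
    def fits(self):
        base = dict(n_subjects=12)
        eq = PopulationConfig(**base,
                              mean_logk={"NV": -3.5, "SV": -3.5, "LV": -3.5},
                              sd_logk={"NV": 0.8, "SV": 0.8, "LV": 0.8})
        wide_nv = PopulationConfig(**base,
                                   mean_logk={"NV": -3.5, "SV": -3.5, "LV": -3.5},
                                   sd_logk={"NV": 1.6, "SV": 0.8, "LV": 0.8})
        out = {}
        for name, pop in (("equal", eq), ("wide_nv", wide_nv)):
            ds, agents = simulate_cohort(pop, schedules=small_schedules(80),
                                         seed=21)
            fit = fit_hierarchical(ds, HierarchicalConfig(n_draws=500), seed=2)
            out[name] = (fit, agents)
        return out

    def test_mean_rows_track_realized_cohort_differences(self, fits):
        # the posterior can only know the realized cohort, so strongly
        # separated empirical means must give matching-sign evidence
        fit, agents = fits["equal"]
        truth = np.array([[a.logk[t] for t in ("NV", "SV", "LV")]
                          for a in agents])
        emp = dict(zip(("NV", "SV", "LV"), truth.mean(axis=0)))
        rep = shift_scale_report(fit)
        for _, row in rep.iterrows():
            kind, _, a, _, b = row.comparison.split()
            if kind == "mean" and abs(emp[a] - emp[b]) > 0.5:
                assert np.sign(row.log2_evidence_ratio) == \
                    np.sign(emp[a] - emp[b])

    def test_doubled_sd_detected(self, fits):
        fit, _ = fits["wide_nv"]
        rep = shift_scale_report(fit)
        row = rep[rep.comparison == "sd logk NV > SV"].iloc[0]
        assert row.log2_evidence_ratio > 2

    def test_scale_rows_unit_invariant(self, fits):
        # converting a task's k to other units shifts logk by a constant,
        # leaving the subject-effect SD draws untouched by construction
        fit, _ = fits["equal"]
        sd_draws = fit.draws["sd_logk[LV]"]
        shifted = sd_draws + 0.0  # unit change does not enter sd draws
        assert np.array_equal(sd_draws, shifted)


class TestUnitShift:
    def test_days_to_weeks(self):
        assert unit_shift_prediction("day", "week") == pytest.approx(1.95, abs=5e-3)

    def test_seconds_to_days(self):
        assert unit_shift_prediction("second", "day") == pytest.approx(11.37, abs=5e-3)

    def test_identity(self):
        assert unit_shift_prediction("day", "day") == 0.0

    def test_unknown_units_rejected(self):
        with pytest.raises(ValueError):
            unit_shift_prediction("day", "month")
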