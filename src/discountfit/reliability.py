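"""Cross-task reliability statistics.

Answers the question "do subjects keep their rank order of impulsivity
across task contexts?": correlations of per-subject log discount
factors with confidence intervals, a simulation-based attenuation
correction (dividing the observed rank correlation by the maximum
attainable given estimation noise), dependent-correlation comparisons
(Steiger / Williams), bootstrap and permutation tests, cross-task
regressions with nested likelihood-ratio tests, and the
time-horizon/verbal variance-decomposition mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import ModelSpec
from .synth import AgentParams, ScheduleConfig, make_offer_schedule, simulate_choices
from .subject_fit import fit_subject_mle


def correlation_with_ci(x, y, method: str = "pearson", n_boot: int = 10000,
                        seed: int = 0) -> dict:
    """Correlation with a 95% CI.

    Pearson CIs use the Fisher z transform; Spearman CIs use a
    percentile bootstrap (``n_boot`` resamples) since no exact closed
    form exists.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    n = len(x)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        z = np.arctanh(r)
        hw = 1.959963984540054 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - hw), np.tanh(z + hw)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = stats.spearmanr(x[idx[i]], y[idx[i]]).statistic
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "ci95": (float(lo), float(hi)),
            "n": n, "method": method}


@dataclass(frozen=True)
class CeilingSimConfig:
    """Configuration of the attenuation-ceiling simulation.

    Agent pairs share identical true log(k) ranks across two tasks (the
    same draw enters both), with task-appropriate trial counts and
    noise, so any shortfall of the recovered rank correlation from 1 is
    pure estimation noise.
    """

    schedule_a: ScheduleConfig
    schedule_b: ScheduleConfig
    n_subjects: int = 63
    mean_logk_a: float = -3.2
    mean_logk_b: float = -3.2
    sd_logk: float = 1.0
    tau_a: float = 0.8
    tau_b: float = 0.8
    n_replicates: int = 500
    model: ModelSpec = field(default_factory=ModelSpec)


def correlation_ceiling(config: CeilingSimConfig, seed: int = 0) -> dict:
    """Expected maximum rank correlation given estimation noise.

    Simulates cohorts whose true logk agree perfectly across the two
    tasks, runs the same MLE pipeline used for observed data on both,
    and averages the resulting Spearman correlations.
    """
    rng = np.random.default_rng(seed)
    ceilings = np.empty(config.n_replicates)
    for rep in range(config.n_replicates):
        z = rng.standard_normal(config.n_subjects)
        est = np.empty((config.n_subjects, 2))
        for i in range(config.n_subjects):
            for j, (sched, mean, tau) in enumerate([
                    (config.schedule_a, config.mean_logk_a, config.tau_a),
                    (config.schedule_b, config.mean_logk_b, config.tau_b)]):
                agent = AgentParams(
                    subject_id=f"c{i}", logk={sched.task: mean + config.sd_logk * z[i]},
                    tau={sched.task: tau})
                trials = simulate_choices(agent, make_offer_schedule(sched, rng),
                                          config.model, rng)
                fit = fit_subject_mle(trials, config.model, n_starts=3,
                                      seed=int(rng.integers(2 ** 31)),
                                      compute_se=False)
                est[i, j] = fit.logk if fit.flag is None else np.nan
        ok = ~np.isnan(est).any(axis=1)
        ceilings[rep] = stats.spearmanr(est[ok, 0], est[ok, 1]).statistic
    return {"ceiling": float(np.mean(ceilings)),
            "ceiling_sd": float(np.std(ceilings, ddof=1)) if config.n_replicates > 1 else 0.0,
            "n_replicates": config.n_replicates}


def corrected_rank_correlation(observed_r: float, ceiling: float,
                               observed_ci: tuple | None = None) -> dict:
    """Attenuation-corrected rank correlation: observed / ceiling.

    Values are capped at 1 (with a flag) when the observed correlation
    exceeds the simulation ceiling. An observed CI, if given, is
    rescaled by the same factor.
    """
    if ceiling <= 0:
        raise ValueError("correlation ceiling must be > 0")
    raw = observed_r / ceiling
    capped = raw > 1.0
    out = {"corrected_r": float(min(raw, 1.0)), "ceiling": float(ceiling),
           "observed_r": float(observed_r), "capped": bool(capped)}
    if observed_ci is not None:
        out["corrected_ci95"] = tuple(float(min(c / ceiling, 1.0)) for c in observed_ci)
    return out


def compare_dependent_correlations(r12: float, r13: float, r23: float,
                                   n: int) -> dict:
    """Compare two overlapping dependent correlations (r12 vs r13 sharing
    variable 1, with r23 between the non-shared variables).

    Implements Steiger's (1980) z̄* (on the Fisher scale with a pooled
    correlation) and Williams' t (n - 3 df); both two-sided.
    """
    for r in (r12, r13, r23):
        if abs(r) >= 1:
            raise ValueError("degenerate correlation |r| = 1")
    if n < 4:
        raise ValueError("need n >= 4")
    rbar = 0.5 * (r12 + r13)
    det = (1 - r12 ** 2 - r13 ** 2 - r23 ** 2) + 2 * r12 * r13 * r23
    # Steiger: covariance of the Fisher z's via psi at the pooled r
    psi = (r23 * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r23 ** 2))
    c = psi / (1 - rbar ** 2) ** 2
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    z_stat = (z12 - z13) * np.sqrt((n - 3) / (2 * (1 - c)))
    z_p = 2 * stats.norm.sf(abs(z_stat))
    # Williams' t
    t_num = (r12 - r13) * np.sqrt((n - 1) * (1 + r23))
    t_den = np.sqrt(2 * det * (n - 1) / (n - 3)
                    + rbar ** 2 * (1 - r23) ** 3)
    t_stat = t_num / t_den
    t_p = 2 * stats.t.sf(abs(t_stat), df=n - 3)
    return {"steiger_z": float(z_stat), "steiger_p": float(z_p),
            "williams_t": float(t_stat), "williams_p": float(t_p), "n": n}


def bootstrap_test(a, b=None, statistic: str = "mean", n_boot: int = 10000,
                   paired: bool = False, seed: int = 0) -> dict:
    """Bootstrap / permutation test, seed-deterministic.

    One sample: locate 0 in the bootstrap distribution of the statistic
    (two-sided). Two unpaired samples: same, on the statistic
    difference with each group resampled. Two paired samples:
    sign-flip permutation test of the mean difference.
    """
    stat_fn = {"mean": np.mean, "median": np.median,
               "variance": lambda v, axis=None: np.var(v, ddof=1, axis=axis)}[statistic]
    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need a 1-d sample with n >= 2")
    degenerate = False
    if b is None:
        boots = stat_fn(a[rng.integers(0, len(a), size=(n_boot, len(a)))], axis=1)
        observed = stat_fn(a)
    elif not paired:
        b = np.asarray(b, float)
        boots = (stat_fn(a[rng.integers(0, len(a), size=(n_boot, len(a)))], axis=1)
                 - stat_fn(b[rng.integers(0, len(b), size=(n_boot, len(b)))], axis=1))
        observed = stat_fn(a) - stat_fn(b)
    else:
        b = np.asarray(b, float)
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        d = a - b
        observed = float(np.mean(d))
        signs = rng.choice([-1.0, 1.0], size=(n_boot, len(d)))
        null = np.mean(signs * d[None, :], axis=1)
        if np.all(d == 0):
            degenerate = True
        p = float((np.sum(np.abs(null) >= abs(observed) - 1e-15) + 1) / (n_boot + 1))
        return {"p": min(p, 1.0), "observed": observed, "distribution": null,
                "degenerate": degenerate, "kind": "paired-permutation"}
    if np.std(boots) == 0:
        degenerate = True
        p = 1.0 if boots[0] == 0 else 0.0
    else:
        frac_le = np.mean(boots <= 0)
        frac_ge = np.mean(boots >= 0)
        p = float(min(1.0, 2 * min(frac_le, frac_ge)))
    return {"p": p, "observed": float(observed), "distribution": boots,
            "degenerate": degenerate, "kind": "bootstrap"}


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    lr_tests: dict = field(default_factory=dict)
    aic: float = np.nan
    loglik: float = np.nan


def cross_task_regression(logk_table: pd.DataFrame, response_task: str,
                          predictor_tasks, extra_factors: pd.DataFrame | None = None
                          ) -> RegressionResult:
    """OLS of one task's log(k) on the other tasks' log(k).

    ``logk_table`` is wide: one row per subject, one column per task.
    Each column of ``extra_factors`` (aligned on subject) is tested by
    a likelihood-ratio test of the full model against the model with
    that factor dropped — the anchoring / early-choice-consistency
    check.
    """
    import statsmodels.api as sm

    y = logk_table[response_task].to_numpy(float)
    X = logk_table[list(predictor_tasks)].copy()
    if extra_factors is not None:
        for col in extra_factors.columns:
            X[col] = extra_factors[col].to_numpy(float)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design; columns: {list(X.columns)}")
    full = sm.OLS(y, X).fit()
    lr_tests = {}
    if extra_factors is not None:
        for col in extra_factors.columns:
            reduced = sm.OLS(y, X.drop(columns=[col])).fit()
            lr = 2 * (full.llf - reduced.llf)
            lr_tests[col] = {"lr": float(lr), "df": 1,
                             "p": float(stats.chi2.sf(lr, 1))}
    return RegressionResult(
        params=full.params, bse=full.bse, pvalues=full.pvalues,
        r2=float(full.rsquared), fvalue=float(full.fvalue),
        f_pvalue=float(full.f_pvalue), df_model=int(full.df_model),
        df_resid=int(full.df_resid), lr_tests=lr_tests,
        aic=float(full.aic), loglik=float(full.llf))


def gap_variance_mixed_model(logk_long: pd.DataFrame) -> RegressionResult:
    """Variance decomposition of log(k) into the time-horizon and verbal
    gaps: logk ~ days + verbal + (1 | subject), fit by ML.

    ``logk_long`` has columns subjid, task, logk; *days* is true only
    for the long-horizon task (LV), *verbal* for the two verbal tasks
    (SV, LV). LR tests (and AICs) for dropping each factor quantify the
    relative contribution of the two gaps.
    """
    import statsmodels.formula.api as smf

    df = logk_long.copy()
    if df.groupby("subjid")["task"].nunique().min() < 2:
        raise ValueError("each subject needs at least two tasks")
    df["days"] = (df["task"].isin(["LV", "DV", "WV"])).astype(float)
    df["verbal"] = (df["task"] != "NV").astype(float)

    def _fit(formula):
        return smf.mixedlm(formula, df, groups=df["subjid"]).fit(reml=False)

    full = _fit("logk ~ days + verbal")
    lr_tests = {}
    for factor in ("days", "verbal"):
        other = "verbal" if factor == "days" else "days"
        reduced = _fit(f"logk ~ {other}")
        lr = 2 * (full.llf - reduced.llf)
        lr_tests[factor] = {"lr": float(lr), "df": 1,
                            "p": float(stats.chi2.sf(lr, 1)),
                            "aic_reduced": float(-2 * reduced.llf + 2 * (reduced.df_modelwc))}
    aic = float(-2 * full.llf + 2 * full.df_modelwc)
    return RegressionResult(
        params=full.params, bse=full.bse, pvalues=full.pvalues,
        r2=np.nan, fvalue=np.nan, f_pvalue=np.nan,
        df_model=int(full.df_modelwc), df_resid=int(full.df_resid),
        lr_tests=lr_tests, aic=aic, loglik=float(full.llf))


def test_retest_summary(dataset, split: str = "half_block") -> dict:
    """Within-task stability of the model-free later-choice rate.

    Splits each subject's trials into two halves — within each reward
    block (``half_block``) or by session (``session``) — and reports
    the paired Pearson correlation and Wilcoxon signed-rank p-value of
    the per-subject fraction-later values.
    """
    df = dataset.trials
    rows = []
    for (subj, task), g in df.groupby(["subjid", "task"]):
        if split == "half_block":
            first, second = [], []
            for _, blk in g.groupby("block"):
                h = len(blk) // 2
                if h == 0:
                    continue
                first.append(blk["chose_later"].iloc[:h].mean())
                second.append(blk["chose_later"].iloc[h:].mean())
            if not first:
                continue
            a, b = float(np.mean(first)), float(np.mean(second))
        elif split == "session":
            sessions = sorted(g["session"].unique())
            if len(sessions) < 2:
                continue
            half = len(sessions) // 2
            a = g[g["session"].isin(sessions[:half])]["chose_later"].mean()
            b = g[g["session"].isin(sessions[half:])]["chose_later"].mean()
        else:
            raise ValueError(f"unknown split {split!r}")
        rows.append({"subjid": subj, "task": task, "first": a, "second": b})
    tab = pd.DataFrame(rows)
    if len(tab) < 4:
        raise ValueError("not enough subjects with both halves")
    x, y = tab["first"].to_numpy(), tab["second"].to_numpy()
    out = {"table": tab, "n": len(tab)}
    if np.std(x) == 0 or np.std(y) == 0:
        out.update({"pearson_r": np.nan, "flag": "degenerate-constant"})
    else:
        out["pearson_r"] = float(stats.pearsonr(x, y).statistic)
    d = x - y
    if np.all(d == 0):
        out["wilcoxon_p"] = 1.0
    else:
        out["wilcoxon_p"] = float(stats.wilcoxon(x, y).pvalue)
    return out
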