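"""Temporal-context analyses.

Covers three questions about how the task context (seconds vs days,
days vs weeks) reshapes measured discounting:

* shift/scale comparisons of the population log(k) distributions
  between tasks, as posterior evidence ratios;
* unit-shift predictions under the "subjects ignore time units"
  hypothesis (log of the unit ratio);
* the early-trial adaptation analysis: a mixed-effects logistic
  regression of choice on utility difference with an early-trials x
  task interaction, testing whether preferences transiently carry over
  from the previous task's time-horizon.

The mixed logistic model is fit by Laplace-approximate maximum
likelihood with a per-subject random intercept and utility-difference
slope (the statsmodels binomial mixed model is variational-Bayes only,
with no likelihood usable in LR tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

from .core import log_unit_shift
from .data_model import Dataset
from .hierarchical import PosteriorFit, evidence_ratio

EARLY_TRIAL_THRESHOLD = 4  # trials at the start of a task counted as 'early'


def delta_utility(dataset: Dataset, fits: pd.DataFrame,
                  tasks=("SV", "LV"),
                  early_threshold: int = EARLY_TRIAL_THRESHOLD) -> pd.DataFrame:
    """Convert each offer into a per-subject utility difference.

    ``fits`` has columns subjid, task and either ``logk_mean``
    (hierarchical posterior means) or ``logk`` (MLE); DU is
    U_later - U_sooner under hyperbolic discounting at the subject's
    task-specific rate. Subjects without a fitted value are skipped
    (listed under the returned frame's ``attrs['skipped']``).
    """
    col = "logk_mean" if "logk_mean" in fits.columns else "logk"
    key = fits.set_index(["subjid", "task"])[col]
    df = dataset.trials[dataset.trials["task"].isin(tasks)]
    rows, skipped = [], set()
    for (subj, task), g in df.groupby(["subjid", "task"]):
        if (subj, task) not in key.index or not np.isfinite(key.loc[(subj, task)]):
            skipped.add(subj)
            continue
        k = np.exp(key.loc[(subj, task)])
        du = (g["later_mag"] / (1.0 + k * g["later_delay"])) - g["sooner_mag"]
        order = g["trial"].rank(method="first")
        rows.append(pd.DataFrame({
            "subjid": subj, "task": task,
            "trial_index": g["trial"].to_numpy(),
            "early": (order <= early_threshold).to_numpy(),
            "delta_u": du.to_numpy(),
            "chose_later": g["chose_later"].to_numpy(bool),
        }))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["skipped"] = sorted(skipped)
    return out


# ---------------------------------------------------------------------------
# Laplace-approximate mixed-effects logistic regression
# ---------------------------------------------------------------------------

@dataclass
class GlmmResult:
    beta: pd.Series
    beta_se: pd.Series
    cov_re: np.ndarray          # 2x2 random-effect covariance (intercept, slope)
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    flag: str | None = None


class _GlmmEngine:
    """Laplace marginal likelihood of the mixed logistic model.

    Random effects are non-centered: b_n = C z_n with z ~ N(0, I) and C
    the Cholesky factor of the 2x2 covariance (intercept + slope on the
    utility-difference column). The latent modes are warm-started
    between likelihood evaluations, so the outer optimizer pays 1-3
    inner Newton iterations per call. The inner problem (logistic
    likelihood plus quadratic prior) is strictly concave, so undamped
    Newton converges.
    """

    def __init__(self, X, y, subj, slope_col=1):
        self.X, self.y, self.subj = X, y, subj
        self.n_groups = int(subj.max()) + 1
        self.Zt = np.stack([np.ones(len(y)), X[:, slope_col]], axis=1)
        self.z = np.zeros((self.n_groups, 2))

    def neg_marginal(self, params, ridge=0.0):
        X, y, subj, n_groups = self.X, self.y, self.subj, self.n_groups
        p = X.shape[1]
        beta = params[:p]
        s0, s1 = np.exp(params[p]), np.exp(params[p + 1])
        r = np.tanh(params[p + 2])
        C = np.array([[s0, 0.0], [s1 * r, s1 * np.sqrt(max(1 - r * r, 1e-12))]])
        V = self.Zt @ C.T                                # dx/dz per trial
        eta_fix = X @ beta
        z = self.z
        for _ in range(30):
            x = eta_fix + np.einsum("nj,nj->n", V, z[subj])
            mu = expit(x)
            resid = y - mu
            w = mu * (1 - mu)
            g0 = np.bincount(subj, resid * V[:, 0], minlength=n_groups)
            g1 = np.bincount(subj, resid * V[:, 1], minlength=n_groups)
            g = np.stack([g0, g1], axis=1) - z
            if np.max(np.abs(g)) < 1e-9:
                break
            H = np.empty((n_groups, 2, 2))
            H[:, 0, 0] = np.bincount(subj, w * V[:, 0] ** 2, minlength=n_groups) + 1
            H[:, 1, 1] = np.bincount(subj, w * V[:, 1] ** 2, minlength=n_groups) + 1
            H[:, 0, 1] = H[:, 1, 0] = np.bincount(subj, w * V[:, 0] * V[:, 1],
                                                  minlength=n_groups)
            z = z + np.linalg.solve(H, g[:, :, None])[:, :, 0]
        self.z = z
        x = eta_fix + np.einsum("nj,nj->n", V, z[subj])
        ll = y * x - np.logaddexp(0.0, x)
        mu = expit(x)
        w = mu * (1 - mu)
        H = np.empty((n_groups, 2, 2))
        H[:, 0, 0] = np.bincount(subj, w * V[:, 0] ** 2, minlength=n_groups) + 1
        H[:, 1, 1] = np.bincount(subj, w * V[:, 1] ** 2, minlength=n_groups) + 1
        H[:, 0, 1] = H[:, 1, 0] = np.bincount(subj, w * V[:, 0] * V[:, 1],
                                              minlength=n_groups)
        _, logdet = np.linalg.slogdet(H)
        marg = ll.sum() - 0.5 * np.sum(z ** 2) - 0.5 * logdet.sum()
        return -(marg - ridge * np.sum(beta ** 2))


def fit_logistic_glmm(X: np.ndarray, y: np.ndarray, subj: np.ndarray,
                      feature_names, ridge: float = 0.0,
                      compute_se: bool = True) -> GlmmResult:
    """ML fit of a logistic mixed model with correlated per-subject
    random intercept and slope on the second design column."""
    engine = _GlmmEngine(X, y, subj)
    p = X.shape[1]
    x0 = np.zeros(p + 3)
    x0[p:p + 2] = np.log(0.5)
    res = minimize(engine.neg_marginal, x0, args=(ridge,),
                   method="L-BFGS-B", options=dict(maxiter=1000, eps=1e-6))
    flag = None
    if (not res.success) or np.abs(res.x[:p]).max() > 15:
        # probable separation or non-convergence: penalized refit
        flag = "penalized-fallback"
        engine.z[:] = 0.0
        res = minimize(engine.neg_marginal, x0, args=(max(ridge, 1e-3),),
                       method="L-BFGS-B", options=dict(maxiter=1000, eps=1e-6))
    se = np.full(p, np.nan)
    if compute_se:
        # observed information of the Laplace marginal
        eps = 1e-4
        k = len(res.x)
        Hm = np.empty((k, k))
        f = lambda v: engine.neg_marginal(v, ridge)
        f0 = f(res.x)
        for i in range(k):
            xp = res.x.copy(); xp[i] += eps
            xm = res.x.copy(); xm[i] -= eps
            Hm[i, i] = (f(xp) - 2 * f0 + f(xm)) / eps ** 2
            for j in range(i + 1, k):
                xpp = res.x.copy(); xpp[i] += eps; xpp[j] += eps
                xpm = res.x.copy(); xpm[i] += eps; xpm[j] -= eps
                xmp = res.x.copy(); xmp[i] -= eps; xmp[j] += eps
                xmm = res.x.copy(); xmm[i] -= eps; xmm[j] -= eps
                Hm[i, j] = Hm[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps ** 2)
        try:
            cov = np.linalg.inv(0.5 * (Hm + Hm.T))
            se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        except np.linalg.LinAlgError:
            pass
    s0, s1 = np.exp(res.x[p]), np.exp(res.x[p + 1])
    r = np.tanh(res.x[p + 2])
    cov_re = np.array([[s0 ** 2, r * s0 * s1], [r * s0 * s1, s1 ** 2]])
    ll = -res.fun
    n_par = p + 3
    return GlmmResult(beta=pd.Series(res.x[:p], index=feature_names),
                      beta_se=pd.Series(se, index=feature_names),
                      cov_re=cov_re, loglik=float(ll),
                      aic=float(-2 * ll + 2 * n_par), n_obs=len(y),
                      n_groups=int(subj.max()) + 1,
                      converged=bool(res.success), flag=flag)


def _design(records: pd.DataFrame, full: bool):
    du = records["delta_u"].to_numpy(float)
    lv = (records["task"] == "LV").to_numpy(float)
    early = records["early"].to_numpy(float)
    cols = {"intercept": np.ones(len(du)), "delta_u": du, "lv": lv,
            "lv:delta_u": lv * du}
    if full:
        cols["early"] = early
        cols["lv:early"] = lv * early
    X = np.stack(list(cols.values()), axis=1)
    return X, list(cols.keys())


def adaptation_glmm(records: pd.DataFrame, compute_se: bool = True) -> dict:
    """Early-trial adaptation test.

    Full model: choice ~ DU + LV:DU + LV*early + (1 + DU | subject);
    reduced model drops the two early terms. Returns both fits and the
    2-df likelihood-ratio chi-square. A positive ``lv:early``
    coefficient means the short task's early trials look relatively
    more attractive in the later option — the carry-over signature.
    """
    for flag_col in ("early",):
        grp = records.groupby("task")[flag_col].agg(["min", "max"])
        if not ((grp["min"] == 0).all() and (grp["max"] == 1).all()):
            raise ValueError("need both early and late trials in each task")
    y = records["chose_later"].to_numpy(float)
    subj_codes, subj = np.unique(records["subjid"], return_inverse=True)
    X_full, names_full = _design(records, full=True)
    X_red, names_red = _design(records, full=False)
    full = fit_logistic_glmm(X_full, y, subj, names_full, compute_se=compute_se)
    reduced = fit_logistic_glmm(X_red, y, subj, names_red, compute_se=compute_se)
    lr = 2 * (full.loglik - reduced.loglik)
    return {"full": full, "reduced": reduced,
            "lr_chi2": float(max(lr, 0.0)), "df": 2,
            "p": float(stats.chi2.sf(max(lr, 0.0), 2)),
            "n_subjects": len(subj_codes), "n_trials": len(y)}


def shift_scale_report(fit: PosteriorFit) -> pd.DataFrame:
    """Shift (population mean) and scale (subject-effect SD) comparisons
    of log(k) between every task pair, as log2 evidence ratios.

    Comparisons are made in each task's native units; the scale rows
    are invariant to unit changes (a unit conversion shifts log(k) by a
    constant), the mean rows are not — the native-unit convention is
    reported alongside.
    """
    fit.require_converged()
    rows = []
    tasks = fit.tasks
    for i, a in enumerate(tasks):
        for b in tasks[i + 1:]:
            for kind, prefix in (("mean", "mu_logk"), ("sd", "sd_logk")):
                hyp = f"{prefix}[{a}] > {prefix}[{b}]"
                res = evidence_ratio(fit, hyp)
                rows.append({
                    "comparison": f"{kind} logk {a} > {b}",
                    "posterior_prob": res.posterior_prob,
                    "log2_evidence_ratio": res.log2_evidence_ratio,
                    "capped": res.capped,
                    "units": "native per task",
                })
    return pd.DataFrame(rows)


def unit_shift_prediction(u_from: str, u_to: str) -> float:
    """Predicted log(k) shift if subjects ignored time units entirely.

    A subject treating '1 week' exactly like '1 day' has the same
    k-number in both unit systems, so converting to common units shifts
    log(k) by ln(unit ratio): days -> weeks gives ln 7 = 1.95; seconds
    -> days gives ln 86400 = 11.37.
    """
    return log_unit_shift(u_from, u_to)
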