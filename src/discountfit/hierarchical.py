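"""Hierarchical Bayesian softmax-hyperbolic discounting model.

The model pools choices across subjects: population-level log discount
factors and log decision noise per task, plus zero-mean per-subject
deviations — correlated across tasks for log(k) (non-centered
parameterization with a Cholesky-factored correlation), and a single
shared deviation for noise:

    logk[n, t]  = mu_logk[t] + (diag(sd_logk) . L . z[n])[t]
    tau[n, t]   = exp(mu_logtau[t] + sd_logtau * u[n])
    P(later)    = logistic((V/(1 + k*T) - S) / tau)

The expanded model adds a per-subject *reward scaling* rho with one
level per time-horizon (short/long) that multiplies both offers'
magnitudes.

Inference: the joint log-posterior (with weakly-informative priors) is
maximized by L-BFGS with analytic gradients; posterior draws come from
the Laplace (Gaussian) approximation at the mode by default, or from an
affine-invariant ensemble sampler (emcee) for an asymptotically exact
cross-check. Both routes expose the same named-draw interface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .core import TASK_HORIZON
from .data_model import Dataset

HORIZONS = ("short", "long")


@dataclass(frozen=True)
class HierarchicalConfig:
    """Sampler and prior settings for the hierarchical fit.

    Priors (link scale): mu_logk ~ N(-3, 3) per task, covering the
    span of log discount rates reported across large populations;
    sd_logk ~ half-N(0, 2); mu_logtau ~ N(0, 1); sd_logtau ~ half-N(0, 1);
    atanh partial correlations ~ N(0, 1); log rho population levels
    ~ N(0, 0.5) (centered at rho = 1) with sd_logrho ~ half-N(0, 0.5).
    """

    tasks: tuple = ("NV", "SV", "LV")
    reward_scaling: bool = False
    n_draws: int = 1000
    method: str = "laplace"            # 'laplace' or 'emcee'
    # priors
    mu_logk_prior: tuple = (-3.0, 3.0)
    sd_logk_scale: float = 2.0
    mu_logtau_prior: tuple = (0.0, 1.0)
    sd_logtau_scale: float = 1.0
    corr_raw_scale: float = 1.0
    mu_logrho_prior: tuple = (0.0, 0.5)
    sd_logrho_scale: float = 0.5
    # emcee settings
    emcee_steps: int = 1500
    emcee_thin: int = 4
    max_rhat: float = 1.05


class _Index:
    """Flat parameter-vector layout for a (tasks, subjects) problem."""

    def __init__(self, n_tasks: int, n_subjects: int, reward_scaling: bool):
        T, N = n_tasks, n_subjects
        self.T, self.N, self.rs = T, N, reward_scaling
        self.P = T * (T - 1) // 2
        cursor = 0

        def block(size):
            nonlocal cursor
            sl = slice(cursor, cursor + size)
            cursor += size
            return sl

        self.mu_logk = block(T)
        self.mu_logtau = block(T)
        self.log_sd_logk = block(T)
        self.log_sd_logtau = block(1)
        self.corr_raw = block(self.P)
        if reward_scaling:
            self.mu_logrho = block(2)
            self.log_sd_logrho = block(2)
        self.z_logk = block(N * T)
        self.u_tau = block(N)
        if reward_scaling:
            self.z_rho = block(N * 2)
        self.dim = cursor


def _chol_from_partial(raw: np.ndarray, T: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial
    correlations (tanh of the unconstrained parameters); always PD."""
    p = np.tanh(raw)
    L = np.zeros((T, T))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, T):
        rem = 1.0
        for j in range(i):
            L[i, j] = p[idx] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(rem, 1e-12))
    return L


@dataclass
class _ModelData:
    """Trial arrays in fitting form (delays stay in task-native units)."""

    y: np.ndarray
    V: np.ndarray
    Td: np.ndarray
    S: np.ndarray
    subj: np.ndarray        # 0..N-1
    task: np.ndarray        # 0..T-1
    horizon: np.ndarray     # 0 short / 1 long
    subjects: list
    tasks: tuple

    @property
    def cell(self):
        return self.subj * len(self.tasks) + self.task

    @classmethod
    def from_dataset(cls, dataset: Dataset, tasks) -> "_ModelData":
        df = dataset.trials
        df = df[df["task"].isin(tasks)]
        subjects = sorted(df["subjid"].unique())
        s_code = {s: i for i, s in enumerate(subjects)}
        t_code = {t: i for i, t in enumerate(tasks)}
        return cls(
            y=df["chose_later"].to_numpy(float),
            V=df["later_mag"].to_numpy(float),
            Td=df["later_delay"].to_numpy(float),
            S=df["sooner_mag"].to_numpy(float),
            subj=df["subjid"].map(s_code).to_numpy(int),
            task=df["task"].map(t_code).to_numpy(int),
            horizon=df["task"].map(lambda t: HORIZONS.index(TASK_HORIZON[t])).to_numpy(int),
            subjects=subjects, tasks=tuple(tasks))


def _halfnormal_logpdf_link(phi: np.ndarray, scale: float):
    """log density of s = exp(phi) ~ half-N(0, scale), including the
    Jacobian of the log link; returns (logp, dlogp/dphi)."""
    s = np.exp(phi)
    logp = -0.5 * (s / scale) ** 2 + phi
    grad = -(s / scale) ** 2 + 1.0
    return logp.sum(), grad


def _unpack(theta: np.ndarray, ix: _Index):
    out = {
        "mu_logk": theta[ix.mu_logk],
        "mu_logtau": theta[ix.mu_logtau],
        "sd_logk": np.exp(theta[ix.log_sd_logk]),
        "sd_logtau": float(np.exp(theta[ix.log_sd_logtau][0])),
        "corr_raw": theta[ix.corr_raw],
        "z": theta[ix.z_logk].reshape(ix.N, ix.T),
        "u": theta[ix.u_tau],
    }
    if ix.rs:
        out["mu_logrho"] = theta[ix.mu_logrho]
        out["sd_logrho"] = np.exp(theta[ix.log_sd_logrho])
        out["z_rho"] = theta[ix.z_rho].reshape(ix.N, 2)
    return out


def _log_posterior(theta: np.ndarray, data: _ModelData, ix: _Index,
                   cfg: HierarchicalConfig, want_grad: bool = True):
    """Joint log-posterior and (optionally) its gradient.

    All gradients are analytic except the correlation parameters, which
    use central finite differences of the full objective (there are only
    T(T-1)/2 of them and the non-centered z prior does not involve L).
    """
    p = _unpack(theta, ix)
    T, N = ix.T, ix.N
    L = _chol_from_partial(p["corr_raw"], T)
    A = (p["z"] @ L.T) * p["sd_logk"][None, :]          # (N, T) subject logk effects
    logk = p["mu_logk"][None, :] + A                    # (N, T)
    logtau = p["mu_logtau"][None, :] + p["sd_logtau"] * p["u"][:, None]

    k = np.exp(logk[data.subj, data.task])
    tau = np.exp(logtau[data.subj, data.task])
    if ix.rs:
        logrho = p["mu_logrho"][None, :] + p["sd_logrho"][None, :] * p["z_rho"]
        rho = np.exp(logrho[data.subj, data.horizon])
    else:
        rho = 1.0

    denom = 1.0 + k * data.Td
    u_later = rho * data.V / denom
    x = (u_later - rho * data.S) / tau
    # Bernoulli-logit log-likelihood, stable in both tails
    ll = data.y * x - (np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x))))
    loglik = ll.sum()

    # priors
    m, s0 = cfg.mu_logk_prior
    mt, st = cfg.mu_logtau_prior
    logp = loglik
    logp += -0.5 * np.sum(((p["mu_logk"] - m) / s0) ** 2)
    logp += -0.5 * np.sum(((p["mu_logtau"] - mt) / st) ** 2)
    lp_sdk, g_sdk = _halfnormal_logpdf_link(theta[ix.log_sd_logk], cfg.sd_logk_scale)
    lp_sdt, g_sdt = _halfnormal_logpdf_link(theta[ix.log_sd_logtau], cfg.sd_logtau_scale)
    logp += lp_sdk + lp_sdt
    logp += -0.5 * np.sum((p["corr_raw"] / cfg.corr_raw_scale) ** 2)
    logp += -0.5 * np.sum(p["z"] ** 2) - 0.5 * np.sum(p["u"] ** 2)
    if ix.rs:
        mr, sr = cfg.mu_logrho_prior
        logp += -0.5 * np.sum(((p["mu_logrho"] - mr) / sr) ** 2)
        lp_sdr, g_sdr = _halfnormal_logpdf_link(theta[ix.log_sd_logrho], cfg.sd_logrho_scale)
        logp += lp_sdr
        logp += -0.5 * np.sum(p["z_rho"] ** 2)
    if not want_grad:
        return logp

    grad = np.zeros(ix.dim)
    resid = data.y - expit(x)                           # dll/dx per trial
    NT = N * T
    # logk channel: dx/dlogk = -V*Td*k/denom^2 * rho / tau
    dx_dlogk = -data.V * data.Td * k / denom ** 2 * rho / tau
    G_logk = np.bincount(data.cell, weights=resid * dx_dlogk, minlength=NT).reshape(N, T)
    # logtau channel: dx/dlogtau = -x
    G_logtau = np.bincount(data.cell, weights=-resid * x, minlength=NT).reshape(N, T)

    grad[ix.mu_logk] = G_logk.sum(axis=0) - (p["mu_logk"] - m) / s0 ** 2
    grad[ix.mu_logtau] = G_logtau.sum(axis=0) - (p["mu_logtau"] - mt) / st ** 2
    # A = (z @ L.T) * sd  =>  dA/dlog_sd[t] = A[:, t]
    grad[ix.log_sd_logk] = np.sum(G_logk * A, axis=0) + g_sdk
    grad[ix.log_sd_logtau] = (
        np.sum(G_logtau * (p["sd_logtau"] * p["u"][:, None])) + g_sdt)
    grad[ix.z_logk] = ((G_logk * p["sd_logk"][None, :]) @ L - p["z"]).ravel()
    grad[ix.u_tau] = p["sd_logtau"] * G_logtau.sum(axis=1) - p["u"]
    if ix.rs:
        # dx/dlogrho = x  (rho scales both utilities linearly)
        G_rho_cell = np.bincount(data.subj * 2 + data.horizon,
                                 weights=resid * x, minlength=N * 2).reshape(N, 2)
        grad[ix.mu_logrho] = G_rho_cell.sum(axis=0) - (p["mu_logrho"] - mr) / sr ** 2
        grad[ix.log_sd_logrho] = np.sum(
            G_rho_cell * (p["sd_logrho"][None, :] * p["z_rho"]), axis=0) + g_sdr
        grad[ix.z_rho] = (G_rho_cell * p["sd_logrho"][None, :] - p["z_rho"]).ravel()

    # correlation parameters: central finite differences of the scalar
    eps = 1e-5
    base = ix.corr_raw.start
    for j in range(ix.P):
        tp = theta.copy(); tp[base + j] += eps
        tm = theta.copy(); tm[base + j] -= eps
        grad[base + j] = (_log_posterior(tp, data, ix, cfg, want_grad=False)
                          - _log_posterior(tm, data, ix, cfg, want_grad=False)) / (2 * eps)
    return logp, grad


@dataclass
class PosteriorFit:
    """Posterior draws keyed by parameter name plus diagnostics.

    Named draws include ``mu_logk[TASK]``, ``sd_logk[TASK]``,
    ``mu_logtau[TASK]``, ``sd_logtau``, ``corr[TASK_A,TASK_B]`` and (in
    the expanded model) ``mu_logrho[short|long]``. Subject-level logk
    draws are accessible through :meth:`subject_logk_draws`.
    """

    tasks: tuple
    subjects: list
    method: str
    config: HierarchicalConfig
    draws: dict
    diagnostics: dict
    converged: bool
    data_hash: str
    _theta_draws: np.ndarray = field(repr=False, default=None)
    _ix: _Index = field(repr=False, default=None)
    _map: np.ndarray = field(repr=False, default=None)

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    def require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError(
                "hierarchical fit failed its convergence diagnostics; "
                f"diagnostics={self.diagnostics}")

    def parameter_names(self) -> list:
        return sorted(self.draws)

    def subject_logk_draws(self) -> np.ndarray:
        """(n_draws, N, T) array of subject-level log discount factors."""
        out = np.empty((self._theta_draws.shape[0], self._ix.N, self._ix.T))
        for d, theta in enumerate(self._theta_draws):
            p = _unpack(theta, self._ix)
            L = _chol_from_partial(p["corr_raw"], self._ix.T)
            out[d] = p["mu_logk"][None, :] + (p["z"] @ L.T) * p["sd_logk"][None, :]
        return out

    def subject_logk_mean(self) -> pd.DataFrame:
        """Posterior mean/SD of each subject's log(k) per task."""
        draws = self.subject_logk_draws()
        rows = []
        for i, subj in enumerate(self.subjects):
            for j, task in enumerate(self.tasks):
                rows.append({"subjid": subj, "task": task,
                             "logk_mean": draws[:, i, j].mean(),
                             "logk_sd": draws[:, i, j].std()})
        return pd.DataFrame(rows)

    def predictive_prob(self, dataset: Dataset, max_draws: int | None = None) -> np.ndarray:
        """(n_draws, n_trials) posterior-predictive P(later) for a table
        of trials from the fitted subjects/tasks."""
        data = _ModelData.from_dataset(dataset, self.tasks)
        code = {s: i for i, s in enumerate(self.subjects)}
        if set(data.subjects) - set(self.subjects):
            raise ValueError("dataset contains subjects unseen by the fit")
        remap = np.array([code[s] for s in data.subjects])
        subj = remap[data.subj]
        thetas = self._theta_draws
        if max_draws is not None and len(thetas) > max_draws:
            step = len(thetas) // max_draws
            thetas = thetas[::step][:max_draws]
        P = np.empty((len(thetas), len(data.y)))
        for d, theta in enumerate(thetas):
            p = _unpack(theta, self._ix)
            L = _chol_from_partial(p["corr_raw"], self._ix.T)
            A = (p["z"] @ L.T) * p["sd_logk"][None, :]
            logk = p["mu_logk"][None, :] + A
            logtau = p["mu_logtau"][None, :] + p["sd_logtau"] * p["u"][:, None]
            kk = np.exp(logk[subj, data.task])
            tt = np.exp(logtau[subj, data.task])
            if self._ix.rs:
                logrho = p["mu_logrho"][None, :] + p["sd_logrho"][None, :] * p["z_rho"]
                rr = np.exp(logrho[subj, data.horizon])
            else:
                rr = 1.0
            x = (rr * data.V / (1.0 + kk * data.Td) - rr * data.S) / tt
            P[d] = expit(x)
        return P


def _named_draws(thetas: np.ndarray, ix: _Index, tasks) -> dict:
    draws = {}
    for j, t in enumerate(tasks):
        draws[f"mu_logk[{t}]"] = thetas[:, ix.mu_logk][:, j]
        draws[f"mu_logtau[{t}]"] = thetas[:, ix.mu_logtau][:, j]
        draws[f"sd_logk[{t}]"] = np.exp(thetas[:, ix.log_sd_logk][:, j])
    draws["sd_logtau"] = np.exp(thetas[:, ix.log_sd_logtau][:, 0])
    # pairwise correlations of subject logk effects
    corr = np.empty((len(thetas), ix.P))
    for d in range(len(thetas)):
        L = _chol_from_partial(thetas[d, ix.corr_raw], ix.T)
        R = L @ L.T
        corr[d] = R[np.triu_indices(ix.T, 1)]
    for idx, (a, b) in enumerate(
            [(i, j) for i in range(ix.T) for j in range(i + 1, ix.T)]):
        draws[f"corr[{tasks[a]},{tasks[b]}]"] = corr[:, idx]
    if ix.rs:
        for j, h in enumerate(HORIZONS):
            draws[f"mu_logrho[{h}]"] = thetas[:, ix.mu_logrho][:, j]
            draws[f"sd_logrho[{h}]"] = np.exp(thetas[:, ix.log_sd_logrho][:, j])
    return draws


def _dataset_hash(dataset: Dataset) -> str:
    csv = dataset.trials.to_csv(index=False).encode()
    return hashlib.sha1(csv).hexdigest()[:12]


class _HyperIndex:
    """Layout of the hyperparameter (population-level) vector."""

    def __init__(self, n_tasks: int, reward_scaling: bool):
        T = n_tasks
        self.T, self.rs = T, reward_scaling
        self.P = T * (T - 1) // 2
        self.q = T + 1 + (2 if reward_scaling else 0)   # latents per subject
        cursor = 0

        def block(size):
            nonlocal cursor
            sl = slice(cursor, cursor + size)
            cursor += size
            return sl

        self.mu_logk = block(T)
        self.mu_logtau = block(T)
        self.log_sd_logk = block(T)
        self.log_sd_logtau = block(1)
        self.corr_raw = block(self.P)
        if reward_scaling:
            self.mu_logrho = block(2)
            self.log_sd_logrho = block(2)
        self.dim = cursor


def _eta_logprior(eta: np.ndarray, hix: _HyperIndex, cfg: HierarchicalConfig) -> float:
    m, s0 = cfg.mu_logk_prior
    mt, st = cfg.mu_logtau_prior
    lp = -0.5 * np.sum(((eta[hix.mu_logk] - m) / s0) ** 2)
    lp += -0.5 * np.sum(((eta[hix.mu_logtau] - mt) / st) ** 2)
    lp += _halfnormal_logpdf_link(eta[hix.log_sd_logk], cfg.sd_logk_scale)[0]
    lp += _halfnormal_logpdf_link(eta[hix.log_sd_logtau], cfg.sd_logtau_scale)[0]
    lp += -0.5 * np.sum((eta[hix.corr_raw] / cfg.corr_raw_scale) ** 2)
    if hix.rs:
        mr, sr = cfg.mu_logrho_prior
        lp += -0.5 * np.sum(((eta[hix.mu_logrho] - mr) / sr) ** 2)
        lp += _halfnormal_logpdf_link(eta[hix.log_sd_logrho], cfg.sd_logrho_scale)[0]
    return float(lp)


class _LaplaceEngine:
    """Laplace-approximate marginal likelihood over per-subject latents.

    The subject latents b_n = (z_logk[T], u_tau, [z_rho[2]]) are standard
    normal a priori (non-centered). Given hyperparameters eta, the inner
    mode b*(eta) is found by damped Newton (vectorized across subjects,
    warm-started between calls); the marginal adds the Gaussian
    correction -0.5 log det of each subject's negative Hessian.
    """

    def __init__(self, data: _ModelData, hix: _HyperIndex, cfg: HierarchicalConfig):
        self.data, self.hix, self.cfg = data, hix, cfg
        self.N = len(data.subjects)
        self.b = np.zeros((self.N, hix.q))
        self._cell = data.subj * hix.T + data.task      # (n, t) cell index
        # horizon of each task (tasks map to a unique horizon)
        self._task_horizon = np.array([
            HORIZONS.index(TASK_HORIZON[t]) for t in data.tasks])

    # -- model pieces ---------------------------------------------------
    def _channels(self, eta):
        hix = self.hix
        s = np.exp(eta[hix.log_sd_logk])
        L = _chol_from_partial(eta[hix.corr_raw], hix.T)
        M = L * s[:, None]                      # logk_n = mu + M @ z_n
        sd_lt = float(np.exp(eta[hix.log_sd_logtau][0]))
        sd_r = np.exp(eta[hix.log_sd_logrho]) if hix.rs else None
        return M, sd_lt, sd_r

    def _trial_terms(self, eta, b, derivs=True):
        """Per-trial x, log-lik, and first/second x-derivatives wrt the
        three scalar channels (logk_t, logtau_t, logrho_h)."""
        d, hix = self.data, self.hix
        M, sd_lt, sd_r = self._channels(eta)
        z = b[:, :hix.T]
        u = b[:, hix.T]
        logk = eta[hix.mu_logk][None, :] + z @ M.T
        logtau = eta[hix.mu_logtau][None, :] + sd_lt * u[:, None]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            # extreme latents visited by the line search may overflow;
            # the resulting NaN objective is rejected by the caller
            k = np.exp(logk[d.subj, d.task])
            tau = np.exp(logtau[d.subj, d.task])
            if hix.rs:
                z_rho = b[:, hix.T + 1:]
                logrho = eta[hix.mu_logrho][None, :] + sd_r[None, :] * z_rho
                rho = np.exp(logrho[d.subj, d.horizon])
            else:
                rho = 1.0
            denom = 1.0 + k * d.Td
            x = (rho * d.V / denom - rho * d.S) / tau
            ll = d.y * x - (np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x))))
            if not derivs:
                return ll, None, None, None, None, None, (M, sd_lt, sd_r)
            p = expit(x)
            resid = d.y - p
            h2 = -p * (1.0 - p)
            c1 = -d.V * d.Td * k / denom ** 2 * rho / tau
            dkk = -d.V * d.Td * k * (1.0 - k * d.Td) / denom ** 3 * rho / tau
        return ll, resid, h2, x, c1, dkk, (M, sd_lt, sd_r)

    def _objective_parts(self, eta, b, want_hess=True):
        """Per-subject inner objective, gradient and Hessian (with the
        standard-normal latent prior folded in).

        The three scalar channels per trial (logk of the trial's task,
        logtau via the shared deviation, logrho of the trial's horizon)
        reduce to per-(subject, task) cell sums, so the per-subject
        Hessians assemble from small einsums rather than per-trial
        outer products.
        """
        d, hix, N, T = self.data, self.hix, self.N, self.hix.T
        ll, resid, h2, x, c1, dkk, (M, sd_lt, sd_r) = self._trial_terms(
            eta, b, derivs=want_hess)
        g_subj = np.bincount(d.subj, weights=ll, minlength=N)
        obj = g_subj - 0.5 * np.sum(b ** 2, axis=1)
        if not want_hess:
            return obj, None, None

        NT = N * T
        cell = self._cell

        def cellsum(w):
            return np.bincount(cell, weights=w, minlength=NT).reshape(N, T)

        c2 = -x                                  # dx/dlogtau
        # gradient channels
        G1 = cellsum(resid * c1)
        G2 = cellsum(resid * c2)
        grad = np.zeros((N, hix.q))
        grad[:, :T] = G1 @ M
        grad[:, T] = sd_lt * G2.sum(axis=1)
        # Hessian channel pair weights: d2ll/dx2 * ci*cj + dll/dx * d2x
        C11 = cellsum(h2 * c1 * c1 + resid * dkk)
        C12 = cellsum(h2 * c1 * c2 - resid * c1)
        C22 = cellsum(h2 * c2 * c2 + resid * x)
        Hess = np.zeros((N, hix.q, hix.q))
        Hess[:, :T, :T] = np.einsum("nt,ti,tj->nij", C11, M, M)
        zu = (C12 @ M) * sd_lt
        Hess[:, :T, T] = zu
        Hess[:, T, :T] = zu
        Hess[:, T, T] = C22.sum(axis=1) * sd_lt ** 2
        if hix.rs:
            c3 = x                               # dx/dlogrho
            G3 = cellsum(resid * c3)
            C13 = cellsum(h2 * c1 * c3 + resid * c1)
            C23 = cellsum(h2 * c2 * c3 - resid * x)
            C33 = cellsum(h2 * c3 * c3 + resid * x)
            for t in range(T):
                col = T + 1 + self._task_horizon[t]
                sr = sd_r[self._task_horizon[t]]
                grad[:, col] += sr * G3[:, t]
                blk = np.outer(np.ones(N), M[t]) * (C13[:, t] * sr)[:, None]
                Hess[:, :T, col] += blk
                Hess[:, col, :T] += blk
                Hess[:, T, col] += C23[:, t] * sd_lt * sr
                Hess[:, col, T] += C23[:, t] * sd_lt * sr
                Hess[:, col, col] += C33[:, t] * sr ** 2
        grad -= b
        Hess -= np.eye(hix.q)[None, :, :]
        return obj, grad, Hess

    def solve_inner(self, eta, tol=1e-8, max_iter=50):
        """Damped Newton for the latent modes, vectorized over subjects.

        The per-subject negative Hessian is eigenvalue-floored to keep
        every step an ascent direction; a per-subject backtracking line
        search guards the saddle-free updates.
        """
        b = self.b.copy()
        b[~np.isfinite(b).all(axis=1)] = 0.0
        obj, grad, Hess = self._objective_parts(eta, b)
        for _ in range(max_iter):
            # subjects with non-finite curvature (overflow at extreme
            # latents) restart from the prior mode
            bad = ~(np.isfinite(obj)
                    & np.isfinite(grad).all(axis=1)
                    & np.isfinite(Hess).all(axis=(1, 2)))
            if bad.any():
                b[bad] = 0.0
                obj, grad, Hess = self._objective_parts(eta, b)
                bad = ~(np.isfinite(obj)
                        & np.isfinite(grad).all(axis=1)
                        & np.isfinite(Hess).all(axis=(1, 2)))
                if bad.any():
                    break                      # pathological eta: give up
            if np.max(np.abs(grad)) < tol:
                break
            negH = -0.5 * (Hess + Hess.transpose(0, 2, 1))
            w, Q = np.linalg.eigh(negH)
            w = np.clip(w, 1e-2, None)
            step = np.einsum("nij,nj->ni", Q / w[:, None, :],
                             np.einsum("nij,ni->nj", Q, grad))
            scale = np.ones(self.N)
            for _ in range(25):
                b_new = b + scale[:, None] * step
                obj_new, _, _ = self._objective_parts(eta, b_new, want_hess=False)
                worse = ~(obj_new >= obj - 1e-10)          # NaN counts as worse
                if not worse.any() or scale.max() < 1e-8:
                    break
                scale[worse] *= 0.5
            improved = obj_new >= obj - 1e-10
            b = np.where(improved[:, None], b_new, b)
            obj_prev = obj
            obj, grad, Hess = self._objective_parts(eta, b)
            if np.max(np.abs(obj - obj_prev)) < 1e-12 and np.max(np.abs(grad)) > tol:
                break                                      # stalled
        self.b = b.copy()
        return b, obj, grad, Hess

    def log_marginal(self, eta):
        """Laplace-approximate log p(data | eta) + log prior(eta)."""
        b, obj, grad, Hess = self.solve_inner(eta)
        if not (np.isfinite(obj).all() and np.isfinite(Hess).all()):
            # hyperparameters in overflow territory: a finite cliff keeps
            # the (derivative-free) outer optimizer well away
            return -1e10
        negH = -Hess
        sign, logdet = np.linalg.slogdet(negH)
        if np.any(sign <= 0):
            # indefinite curvature at the mode: fall back to a floored
            # eigenvalue determinant (rare, keeps the optimizer moving)
            w = np.linalg.eigvalsh(0.5 * (negH + negH.transpose(0, 2, 1)))
            logdet = np.sum(np.log(np.clip(w, 1e-8, None)), axis=1)
        const = 0.5 * self.hix.q * np.log(2.0 * np.pi)
        lap = obj + const - 0.5 * logdet
        return float(lap.sum()) + _eta_logprior(eta, self.hix, self.cfg)


def _pack_joint(eta, b, ix: _Index, hix: _HyperIndex) -> np.ndarray:
    theta = np.empty(ix.dim)
    theta[ix.mu_logk] = eta[hix.mu_logk]
    theta[ix.mu_logtau] = eta[hix.mu_logtau]
    theta[ix.log_sd_logk] = eta[hix.log_sd_logk]
    theta[ix.log_sd_logtau] = eta[hix.log_sd_logtau]
    theta[ix.corr_raw] = eta[hix.corr_raw]
    if hix.rs:
        theta[ix.mu_logrho] = eta[hix.mu_logrho]
        theta[ix.log_sd_logrho] = eta[hix.log_sd_logrho]
        theta[ix.z_rho] = b[:, hix.T + 1:].ravel()
    theta[ix.z_logk] = b[:, :hix.T].ravel()
    theta[ix.u_tau] = b[:, hix.T]
    return theta


def _hyper_hessian(fun, x, eps=1e-3):
    """Dense central-difference Hessian of a scalar function."""
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / eps ** 2
        for j in range(i + 1, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * eps ** 2)
    return H


def fit_hierarchical(dataset: Dataset,
                     config: HierarchicalConfig = HierarchicalConfig(),
                     seed: int = 0) -> PosteriorFit:
    """Fit the hierarchical model and return posterior draws.

    ``method='laplace'`` (default): hyperparameters are estimated by
    maximizing the Laplace-approximate marginal posterior (subject
    latents integrated out per subject, as in glmmTMB/lme4-style
    mixed-model fitting); posterior draws combine a Gaussian
    approximation on the hyperparameters with each subject's
    conditional Gaussian. ``method='emcee'``: affine-invariant ensemble
    MCMC on the full joint posterior, initialized at the Laplace
    solution; split-group R-hat is checked against ``config.max_rhat``.
    """
    data = _ModelData.from_dataset(dataset, config.tasks)
    ix = _Index(len(config.tasks), len(data.subjects), config.reward_scaling)
    hix = _HyperIndex(len(config.tasks), config.reward_scaling)
    rng = np.random.default_rng(seed)

    engine = _LaplaceEngine(data, hix, config)
    eta0 = np.zeros(hix.dim)
    eta0[hix.mu_logk] = -3.0
    eta0[hix.log_sd_logk] = np.log(0.5)
    eta0[hix.log_sd_logtau] = np.log(0.3)
    if config.reward_scaling:
        eta0[hix.log_sd_logrho] = np.log(0.2)

    res = minimize(lambda e: -engine.log_marginal(e), eta0, method="L-BFGS-B",
                   options=dict(maxiter=500, eps=1e-5))
    eta_star = res.x
    diagnostics = {"opt_success": bool(res.success),
                   "neg_log_marginal": float(res.fun),
                   "dim_hyper": hix.dim, "dim": ix.dim,
                   "n_trials": len(data.y)}

    if config.method == "laplace":
        Hh = _hyper_hessian(lambda e: -engine.log_marginal(e), eta_star)
        w, Q = np.linalg.eigh(0.5 * (Hh + Hh.T))
        # the weakest prior (sd 3 on population logk) alone contributes
        # ~0.1 curvature, so smaller eigenvalues are numerical noise
        w = np.clip(w, 0.05, None)
        scale = Q / np.sqrt(w)[None, :]
        diagnostics["hyper_hessian_min_eig"] = float(w.min())
        # truncate at 4 posterior sd: the Gaussian tail occasionally
        # reaches hyperparameters whose inner problem overflows
        eps_h = np.clip(rng.standard_normal((config.n_draws, hix.dim)), -4, 4)
        etas = eta_star[None, :] + eps_h @ scale.T
        thetas = np.empty((config.n_draws, ix.dim))
        for m, eta in enumerate(etas):
            b_mode, _, grad, Hess = engine.solve_inner(eta, tol=1e-5, max_iter=15)
            if not np.isfinite(grad).all() or np.max(np.abs(grad)) > 1e-2:
                # warm start led the inner solver astray; retry cold
                engine.b = np.zeros_like(engine.b)
                b_mode, _, grad, Hess = engine.solve_inner(eta, tol=1e-6, max_iter=50)
            bad = (~np.isfinite(Hess).all(axis=(1, 2))
                   | ~np.isfinite(b_mode).all(axis=1))
            if bad.any():
                b_mode = b_mode.copy()
                b_mode[bad] = 0.0
                Hess = Hess.copy()
                Hess[bad] = -np.eye(hix.q)
            negH = -Hess
            wb, Qb = np.linalg.eigh(0.5 * (negH + negH.transpose(0, 2, 1)))
            # the standard-normal latent prior alone contributes unit
            # curvature, so anything below that signals a bad mode
            wb = np.clip(wb, 0.5, None)
            epsb = rng.standard_normal((engine.N, hix.q))
            b_draw = b_mode + np.einsum("nij,nj->ni", Qb / np.sqrt(wb)[:, None, :], epsb)
            thetas[m] = _pack_joint(eta, b_draw, ix, hix)
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1.0
        diagnostics["rhat_max"] = None
    elif config.method == "emcee":
        import emcee

        b_mode, _, _, _ = engine.solve_inner(eta_star)
        mode = _pack_joint(eta_star, b_mode, ix, hix)
        n_walkers = max(2 * ix.dim + 2, 64)
        p0 = mode[None, :] + 0.01 * rng.standard_normal((n_walkers, ix.dim))
        sampler = emcee.EnsembleSampler(
            n_walkers, ix.dim,
            lambda th: _log_posterior(th, data, ix, config, want_grad=False))
        start = emcee.State(p0, random_state=np.random.RandomState(seed))
        sampler.run_mcmc(start, config.emcee_steps, progress=False)
        burn = config.emcee_steps // 2
        chain = sampler.get_chain(discard=burn, thin=config.emcee_thin)  # (S, W, dim)
        thetas = chain.reshape(-1, ix.dim)
        if len(thetas) > config.n_draws:
            sel = rng.choice(len(thetas), size=config.n_draws, replace=False)
            thetas = thetas[sel]
        # R-hat over 4 walker groups (pseudo-chains), population-level
        # parameters only
        import arviz as az

        pop = np.arange(ix.mu_logk.start, ix.corr_raw.stop)
        ch = chain[:, :, pop]                      # (steps, walkers, p)
        groups = np.array_split(np.arange(ch.shape[1]), 4)
        stacked = np.stack([ch[:, g, :].reshape(-1, len(pop)) for g in groups])
        rhat = az.rhat(az.convert_to_dataset(stacked))
        rhat_max = float(np.nanmax(rhat.to_array().values))
        diagnostics["rhat_max"] = rhat_max
        diagnostics["acceptance_fraction"] = float(np.mean(sampler.acceptance_fraction))
        converged = rhat_max <= config.max_rhat
    else:
        raise ValueError(f"unknown method {config.method!r}")

    fit = PosteriorFit(tasks=tuple(config.tasks), subjects=data.subjects,
                       method=config.method, config=config,
                       draws=_named_draws(thetas, ix, config.tasks),
                       diagnostics=diagnostics, converged=converged,
                       data_hash=_dataset_hash(dataset),
                       _theta_draws=thetas, _ix=ix)
    return fit


def fit_reward_scaling_model(dataset: Dataset,
                             config: HierarchicalConfig = HierarchicalConfig(),
                             seed: int = 0) -> PosteriorFit:
    """The expanded model: per-subject reward scaling with a short and a
    long horizon level (adds 2 population and 2N subject parameters)."""
    return fit_hierarchical(dataset, replace(config, reward_scaling=True), seed=seed)


def posterior_summary(fit: PosteriorFit, parameter: str,
                      levels=(0.80, 0.95)) -> dict:
    """Posterior mean and central credible intervals of a named parameter."""
    fit.require_converged()
    if parameter not in fit.draws:
        raise KeyError(f"unknown parameter {parameter!r}; "
                       f"available: {fit.parameter_names()}")
    d = fit.draws[parameter]
    out = {"mean": float(d.mean()), "sd": float(d.std())}
    for lev in levels:
        lo, hi = np.quantile(d, [(1 - lev) / 2, 1 - (1 - lev) / 2])
        out[f"ci{int(round(lev * 100))}"] = (float(lo), float(hi))
    return out


@dataclass
class HypothesisResult:
    hypothesis: str
    posterior_prob: float
    evidence_ratio: float
    log2_evidence_ratio: float
    capped: bool


def evidence_ratio(fit: PosteriorFit, hypothesis: str) -> HypothesisResult:
    """One-sided hypothesis test from posterior draws.

    ``hypothesis`` is ``"name_a > name_b"`` (or ``<``) over named
    parameters. The evidence ratio is the posterior odds
    P(hypothesis)/P(alternative), capped at the draw resolution.
    """
    fit.require_converged()
    for op in (" > ", " < "):
        if op in hypothesis:
            lhs, rhs = hypothesis.split(op)
            break
    else:
        raise ValueError("hypothesis must look like 'a > b' or 'a < b'")
    a, b = fit.draws[lhs.strip()], fit.draws[rhs.strip()]
    sat = (a > b) if op == " > " else (a < b)
    n = len(sat)
    p = float(np.mean(sat))
    capped = p in (0.0, 1.0)
    # cap at the resolution of the draws
    p_c = min(max(p, 1.0 / (n + 1)), n / (n + 1))
    ratio = p_c / (1.0 - p_c)
    return HypothesisResult(hypothesis=hypothesis, posterior_prob=p,
                            evidence_ratio=ratio,
                            log2_evidence_ratio=float(np.log2(ratio)),
                            capped=capped)


def bayes_r2(fit: PosteriorFit, dataset: Dataset, per_subject: bool = False,
             max_draws: int = 200):
    """Bayesian R-squared of the posterior-predictive choice probabilities.

    Per draw: var(p) / (var(p) + mean(p * (1 - p))) — the explained
    variance over the modelled Bernoulli residual variance. Returns the
    posterior mean and sd of R2 (pooled), or a per-subject table.
    """
    fit.require_converged()
    P = fit.predictive_prob(dataset, max_draws=max_draws)
    df = dataset.trials[dataset.trials["task"].isin(fit.tasks)]

    def _r2(block):
        var_fit = block.var(axis=1)
        var_res = (block * (1.0 - block)).mean(axis=1)
        return var_fit / (var_fit + var_res)

    if not per_subject:
        r2 = _r2(P)
        return {"mean": float(r2.mean()), "sd": float(r2.std())}
    rows = []
    subj = df["subjid"].to_numpy()
    for s in np.unique(subj):
        r2 = _r2(P[:, subj == s])
        rows.append({"subjid": s, "r2_mean": float(r2.mean()),
                     "r2_sd": float(r2.std())})
    return pd.DataFrame(rows)


def kfold_ic(dataset: Dataset, config: HierarchicalConfig = HierarchicalConfig(),
             k: int = 10, seed: int = 0, max_draws: int = 200) -> dict:
    """K-fold cross-validated information criterion, -2 * elpd.

    Folds are stratified by subject x task so every training set retains
    all subjects. Each fold is refit from scratch; the held-out expected
    log posterior predictive density (elpd) accumulates
    log mean_draws p(y_i | theta). Returns the IC and the pointwise
    contributions (aligned with the dataset row order) for paired
    comparisons.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = dataset.trials[dataset.trials["task"].isin(config.tasks)].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(df), int)
    for _, idx in df.groupby(["subjid", "task"]).indices.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % k
    pointwise = np.empty(len(df))
    for j in range(k):
        train = Dataset(trials=df.loc[fold != j].reset_index(drop=True))
        test = df.loc[fold == j].reset_index(drop=True)
        fit = fit_hierarchical(train, config, seed=seed + 1000 + j)
        if not fit.converged:
            raise RuntimeError(f"fold {j} failed convergence: {fit.diagnostics}")
        P = fit.predictive_prob(Dataset(trials=test), max_draws=max_draws)
        y = test["chose_later"].to_numpy(float)
        dens = np.where(y[None, :] > 0.5, P, 1.0 - P)
        dens = np.clip(dens, 1e-300, None)
        # log mean over draws, stable
        mx = dens.max(axis=0)
        pointwise[fold == j] = np.log(mx) + np.log(np.mean(dens / mx[None, :], axis=0))
    elpd = float(pointwise.sum())
    return {"kfoldic": -2.0 * elpd, "elpd": elpd, "pointwise": pointwise,
            "k": k, "n": len(df)}


def kfold_compare(res_a: dict, res_b: dict) -> dict:
    """Delta KfoldIC (a - b) with a paired SE over pointwise contributions.

    Negative favors model a (lower IC is better).
    """
    if res_a["n"] != res_b["n"]:
        raise ValueError("KfoldIC comparison requires identical data")
    diff = -2.0 * (res_a["pointwise"] - res_b["pointwise"])
    n = len(diff)
    se = float(np.sqrt(n * diff.var(ddof=1)))
    return {"delta_kfoldic": float(diff.sum()), "se": se}
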