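"""Synthetic cohort generator.

Emulates the structure of a three-task intertemporal-choice study:
blocked offer schedules (5 delays x 5 magnitudes against a fixed
immediate option of 4 coins), 63 subjects whose log discount factors
are correlated across tasks, per-subject softmax decision noise, and
smaller-later catch offers (25% of later offers in the non-verbal task,
10% in the verbal tasks).

Every public function takes an explicit seed or Generator; there is no
hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TASK_HORIZON, TASK_UNITS, ModelSpec, choice_prob
from .data_model import Dataset

DEFAULT_DELAYS = (3.0, 6.5, 14.0, 30.0, 64.0)
DEFAULT_MAGNITUDES = (1.0, 2.0, 5.0, 8.0, 10.0)

#: Per-task defaults: total trials, sessions they are spread over, and the
#: share of later offers that are smaller-later catch trials. The
#: non-verbal task spans three sessions (the first is excluded from
#: fitting, leaving 200 post-learning trials); verbal tasks span the two
#: verbal sessions with ~160 trials each. The days/weeks control tasks
#: run in a single session of 200 trials.
_TASK_DEFAULTS = {
    "NV": dict(n_trials=300, sessions=(1, 2, 3), smaller_later_share=0.25,
               delays=DEFAULT_DELAYS),
    "SV": dict(n_trials=160, sessions=(4, 5), smaller_later_share=0.10,
               delays=DEFAULT_DELAYS),
    "LV": dict(n_trials=160, sessions=(4, 5), smaller_later_share=0.10,
               delays=DEFAULT_DELAYS),
    # 5-point roughly log-spaced grids spanning 1-64 days and 1-35 weeks
    "DV": dict(n_trials=200, sessions=(1,), smaller_later_share=0.10,
               delays=(1.0, 3.0, 8.0, 25.0, 64.0)),
    "WV": dict(n_trials=200, sessions=(1,), smaller_later_share=0.10,
               delays=(1.0, 2.0, 5.0, 13.0, 35.0)),
}

DEFAULT_TASKS = ("NV", "SV", "LV")

#: Cross-task correlation of subject-level log(k) effects, task order
#: (NV, SV, LV): strong between the two short tasks, weakest across both
#: the verbal and horizon gaps.
DEFAULT_CORRELATION = np.array([
    [1.0, 0.8, 0.4],
    [0.8, 1.0, 0.6],
    [0.4, 0.6, 1.0],
])


@dataclass(frozen=True)
class ScheduleConfig:
    """Offer-schedule parameters for one task."""

    task: str
    delays: tuple = DEFAULT_DELAYS
    magnitudes: tuple = DEFAULT_MAGNITUDES
    sooner_magnitude: float = 4.0
    n_trials: int = 160
    sessions: tuple = (1,)
    smaller_later_share: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.smaller_later_share <= 1.0):
            raise ValueError("smaller_later_share must be in [0, 1]")
        if len(self.delays) == 0 or len(self.magnitudes) == 0:
            raise ValueError("delays and magnitudes must be non-empty")
        if min(self.delays) <= 0 or min(self.magnitudes) <= 0:
            raise ValueError("delays and magnitudes must be positive")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "ScheduleConfig":
        if task not in _TASK_DEFAULTS:
            raise ValueError(f"no schedule defaults for task {task!r}")
        kwargs = dict(_TASK_DEFAULTS[task])
        kwargs.update(overrides)
        return cls(task=task, **kwargs)

    @property
    def smaller_magnitudes(self) -> tuple:
        return tuple(m for m in self.magnitudes if m < self.sooner_magnitude)

    @property
    def larger_magnitudes(self) -> tuple:
        return tuple(m for m in self.magnitudes if m > self.sooner_magnitude)


def default_schedules(tasks=DEFAULT_TASKS) -> dict:
    return {t: ScheduleConfig.for_task(t) for t in tasks}


@dataclass(frozen=True)
class PopulationConfig:
    """Population from which agents are drawn.

    Subject log(k) effects are jointly normal across tasks with the
    configured correlation; decision noise gets one lognormal subject
    deviation shared across tasks (on top of per-task means); reward
    scaling rho is per time-horizon (short/long) and defaults to 1.
    """

    n_subjects: int = 63
    tasks: tuple = DEFAULT_TASKS
    mean_logk: dict = field(default_factory=lambda: {"NV": -3.2, "SV": -3.49, "LV": -3.95})
    sd_logk: dict = field(default_factory=lambda: {"NV": 1.0, "SV": 1.0, "LV": 1.0})
    cross_task_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATION.copy())
    mean_tau: dict = field(default_factory=lambda: {"NV": 1.5, "SV": 0.8, "LV": 0.8})
    sd_logtau: float = 0.3
    mean_rho: dict = field(default_factory=lambda: {"short": 1.0, "long": 1.0})
    sd_logrho: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.cross_task_correlation, float)
        if R.shape != (len(self.tasks),) * 2:
            raise ValueError("correlation matrix shape must match number of tasks")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        for t in self.tasks:
            if self.sd_logk[t] < 0:
                raise ValueError("sd_logk must be >= 0")
            if self.mean_tau[t] <= 0:
                raise ValueError("mean_tau must be > 0")


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth parameters of one simulated subject."""

    subject_id: str
    logk: dict            # task -> log discount rate, 1/task-unit
    tau: dict             # task -> softmax noise (> 0)
    alpha: float = 1.0    # utility curvature
    rho: dict = field(default_factory=lambda: {"short": 1.0, "long": 1.0})

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.tau.values()):
            raise ValueError("tau must be > 0")
        if self.alpha <= 0 or any(v <= 0 for v in self.rho.values()):
            raise ValueError("alpha and rho must be > 0")


def _as_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _magnitude_counts(config: ScheduleConfig, n: int) -> dict:
    """Trials per later magnitude for a session of n trials.

    Smaller-later mass (split as evenly as possible between the
    smaller magnitudes) is exactly round(n * share); all larger-later
    magnitudes are equally likely.
    """
    small, large = config.smaller_magnitudes, config.larger_magnitudes
    counts = {}
    n_small = int(round(n * config.smaller_later_share)) if small else 0
    if small:
        base, extra = divmod(n_small, len(small))
        for i, m in enumerate(small):
            counts[m] = base + (1 if i < extra else 0)
    n_large = n - n_small
    base, extra = divmod(n_large, len(large))
    for i, m in enumerate(large):
        counts[m] = base + (1 if i < extra else 0)
    return counts


def make_offer_schedule(config: ScheduleConfig, seed) -> pd.DataFrame:
    """Build one subject's ordered offer schedule for a task.

    Offers are grouped into magnitude blocks presented in random order,
    with block lengths jittered by +-1 trial around
    n_per_session / n_magnitudes; within a block, delays are randomly
    ordered, cycling through the full delay grid so every
    (magnitude, delay) combination occurs whenever a magnitude has at
    least as many trials as there are delays.
    """
    rng = _as_rng(seed)
    n_distinct = len(config.delays) * len(config.magnitudes)
    if config.n_trials < n_distinct:
        raise ValueError(
            f"n_trials={config.n_trials} is fewer than the {n_distinct} distinct offers")

    n_sessions = len(config.sessions)
    base_n, extra = divmod(config.n_trials, n_sessions)
    session_sizes = [base_n + (1 if i < extra else 0) for i in range(n_sessions)]

    # Per-magnitude delay sequences for the whole task: repeated reshuffled
    # copies of the delay grid, consumed session by session.
    total_counts = {}
    for n_s in session_sizes:
        for m, c in _magnitude_counts(config, n_s).items():
            total_counts[m] = total_counts.get(m, 0) + c
    delay_seq = {}
    for m, c in total_counts.items():
        reps = []
        while len(reps) < c:
            reps.extend(rng.permutation(config.delays))
        delay_seq[m] = list(reps[:c])

    rows = []
    trial_idx = 0
    block_idx = 0
    base_block = max(1, int(round(base_n / len(config.magnitudes))))
    for session, n_s in zip(config.sessions, session_sizes):
        counts = _magnitude_counts(config, n_s)
        blocks = []
        for m, c in counts.items():
            remaining = c
            while remaining > 0:
                length = int(np.clip(base_block + rng.integers(-1, 2), 1, remaining))
                if remaining - length < len(config.delays) // 2:
                    length = remaining  # avoid stub blocks
                blocks.append((m, length))
                remaining -= length
        order = rng.permutation(len(blocks))
        for bi in order:
            m, length = blocks[bi]
            block_idx += 1
            for _ in range(length):
                trial_idx += 1
                rows.append({
                    "task": config.task, "session": session, "block": block_idx,
                    "trial": trial_idx, "sooner_mag": config.sooner_magnitude,
                    "later_mag": m, "later_delay": delay_seq[m].pop(0),
                    "delay_unit": TASK_UNITS[config.task],
                })
    return pd.DataFrame(rows)


def sample_population(config: PopulationConfig, seed) -> list:
    """Draw agents with correlated per-task log(k) subject effects."""
    rng = _as_rng(seed)
    R = np.asarray(config.cross_task_correlation, float)
    # eigendecomposition square root: tolerant of semi-definite matrices
    w, V = np.linalg.eigh(R)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((config.n_subjects, len(config.tasks))) @ root.T
    u_tau = rng.standard_normal(config.n_subjects)
    z_rho = rng.standard_normal((config.n_subjects, 2))
    agents = []
    width = max(2, len(str(config.n_subjects)))
    for i in range(config.n_subjects):
        logk = {t: config.mean_logk[t] + config.sd_logk[t] * z[i, j]
                for j, t in enumerate(config.tasks)}
        tau = {t: float(config.mean_tau[t] * np.exp(config.sd_logtau * u_tau[i]))
               for t in config.tasks}
        rho = {h: float(config.mean_rho[h] * np.exp(config.sd_logrho * z_rho[i, j]))
               for j, h in enumerate(("short", "long"))}
        agents.append(AgentParams(subject_id=f"s{i + 1:0{width}d}",
                                  logk=logk, tau=tau, rho=rho))
    return agents


def simulate_choices(agent: AgentParams, schedule: pd.DataFrame,
                     model: ModelSpec, seed) -> pd.DataFrame:
    """Simulate one agent's choices on a schedule.

    Each trial's choice is a Bernoulli draw with P(later) from the
    model's choice rule applied to the agent's utilities.
    """
    rng = _as_rng(seed)
    task = schedule["task"].iloc[0]
    k = float(np.exp(agent.logk[task]))
    tau = agent.tau[task]
    if tau <= 0:
        raise ValueError("stochastic choice requires tau > 0")
    rho = agent.rho[TASK_HORIZON[task]]
    p = choice_prob(model, schedule["later_mag"].to_numpy(),
                    schedule["later_delay"].to_numpy(),
                    schedule["sooner_mag"].to_numpy(),
                    k, tau, alpha=agent.alpha, rho=rho)
    out = schedule.copy()
    out.insert(0, "subjid", agent.subject_id)
    out["chose_later"] = rng.random(len(out)) < p
    return out


def simulate_cohort(pop: PopulationConfig = PopulationConfig(),
                    schedules: dict | None = None,
                    model: ModelSpec = ModelSpec(),
                    seed: int = 0):
    """Simulate a full study-shaped dataset.

    Returns (Dataset, agents). Each subject gets an independent offer
    schedule per task (as in the study, where block order and jitter
    differ across subjects). Deterministic given the seed.
    """
    if schedules is None:
        schedules = default_schedules(pop.tasks)
    root = np.random.SeedSequence(seed)
    pop_seed, choice_seed = root.spawn(2)
    agents = sample_population(pop, np.random.default_rng(pop_seed))
    rng = np.random.default_rng(choice_seed)
    frames = []
    for agent in agents:
        for task in pop.tasks:
            sched = make_offer_schedule(schedules[task], rng)
            frames.append(simulate_choices(agent, sched, model, rng))
    trials = pd.concat(frames, ignore_index=True)
    dataset = Dataset(trials=trials[[
        "subjid", "task", "session", "block", "trial", "sooner_mag",
        "later_mag", "later_delay", "delay_unit", "chose_later"]])
    return dataset, agents
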