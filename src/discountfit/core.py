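"""Discounting algebra: utility families, choice rules, unit conversions.

Everything downstream (per-subject MLE, the hierarchical model, the
context analyses) consumes these functions, so they are all vectorized
over numpy arrays and kept free of any I/O or state.

The model of choice behaviour is: a delayed reward of ``V`` coins at
delay ``T`` has subjective utility ``U = V / (1 + k*T)`` (hyperbolic
discounting with rate ``k``, units 1/time), the immediate option of
``S`` coins has utility ``S``, and the probability of choosing the
later option follows a softmax with decision noise ``tau``:

    P(later) = exp(U_L/tau) / (exp(U_L/tau) + exp(U_S/tau))

Alternative pieces (exponential discounting, a scale-invariant matching
rule, utility curvature ``alpha``, reward scaling ``rho``) are provided
for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# One constants surface for the whole package.
SECONDS_PER_DAY = 86400.0
DAYS_PER_WEEK = 7.0
#: Multiplicative increase of k when moving from large-stake (long-horizon)
#: to small-stake (short-horizon) reward scales (the magnitude effect).
MAGNITUDE_EFFECT_FACTOR = 2.0

#: Seconds per unit of each supported delay unit.
UNIT_SECONDS = {
    "second": 1.0,
    "day": SECONDS_PER_DAY,
    "week": SECONDS_PER_DAY * DAYS_PER_WEEK,
}

#: Native delay unit of each task. NV = non-verbal (seconds), SV = short
#: verbal (seconds), LV = long verbal (days); DV/WV are the days/weeks
#: control tasks.
TASK_UNITS = {
    "NV": "second",
    "SV": "second",
    "LV": "day",
    "DV": "day",
    "WV": "week",
}

#: Time-horizon class of each task, used by the reward-scaling expansion.
TASK_HORIZON = {"NV": "short", "SV": "short", "LV": "long", "DV": "long", "WV": "long"}

UTILITY_FAMILIES = ("hyperbolic", "exponential")
CHOICE_RULES = ("softmax", "matching")

_PROB_FLOOR = 1e-12  # probabilities clipped to [floor, 1-floor] inside logs


@dataclass(frozen=True)
class ModelSpec:
    """A model class: utility family x choice rule, plus optional switches.

    ``curvature`` adds a power ``alpha`` on magnitude ((rho*V)**alpha);
    ``reward_scaling`` multiplies magnitudes by a horizon-level ``rho``.
    Parameter links are fixed: log(k) is unconstrained, tau/alpha/rho are
    fit through log-links.
    """

    utility_family: str = "hyperbolic"
    choice_rule: str = "softmax"
    curvature: bool = False
    reward_scaling: bool = False

    def __post_init__(self) -> None:
        if self.utility_family not in UTILITY_FAMILIES:
            raise ValueError(f"unknown utility family: {self.utility_family!r}")
        if self.choice_rule not in CHOICE_RULES:
            raise ValueError(f"unknown choice rule: {self.choice_rule!r}")

    @property
    def name(self) -> str:
        tags = [self.utility_family, self.choice_rule]
        if self.curvature:
            tags.append("curv")
        if self.reward_scaling:
            tags.append("rho")
        return "-".join(tags)

    @property
    def n_params(self) -> int:
        """Free per-subject parameters (logk, log tau, + optional links)."""
        return 2 + int(self.curvature) + int(self.reward_scaling)

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        parts = name.split("-")
        if len(parts) < 2:
            raise ValueError(f"cannot parse model name {name!r}")
        return cls(
            utility_family=parts[0],
            choice_rule=parts[1],
            curvature="curv" in parts[2:],
            reward_scaling="rho" in parts[2:],
        )


def _check_positive(**kwargs) -> None:
    for label, value in kwargs.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"{label} must be strictly positive")


def hyperbolic_utility(V, T, k, alpha=1.0, rho=1.0):
    """U = (rho*V)**alpha / (1 + k*T).

    With alpha = rho = 1 this is plain hyperbolic discounting. ``T`` is in
    the same time unit as 1/k.
    """
    V, T = np.asarray(V, float), np.asarray(T, float)
    _check_positive(V=V, k=k, alpha=alpha, rho=rho)
    if np.any(T < 0):
        raise ValueError("delay T must be non-negative")
    return (rho * V) ** alpha / (1.0 + np.asarray(k, float) * T)


def exponential_utility(V, T, k, alpha=1.0, rho=1.0):
    """U = (rho*V)**alpha * exp(-k*T) (constant hazard of reward loss)."""
    V, T = np.asarray(V, float), np.asarray(T, float)
    _check_positive(V=V, k=k, alpha=alpha, rho=rho)
    if np.any(T < 0):
        raise ValueError("delay T must be non-negative")
    return (rho * V) ** alpha * np.exp(-np.asarray(k, float) * T)


def utility(spec: ModelSpec, V, T, k, alpha=1.0, rho=1.0):
    fn = hyperbolic_utility if spec.utility_family == "hyperbolic" else exponential_utility
    return fn(V, T, k, alpha=alpha, rho=rho)


def softmax_choice_prob(u_later, u_sooner, tau):
    """P(later) under the shift-invariant softmax rule, overflow-safe."""
    _check_positive(tau=tau)
    x = (np.asarray(u_later, float) - np.asarray(u_sooner, float)) / np.asarray(tau, float)
    # logistic(x), stable in both tails
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return out


def matching_choice_prob(u_later, u_sooner, tau):
    """P(later) under the scale-invariant matching (Luce power) rule.

    P = U_L**(1/tau) / (U_L**(1/tau) + U_S**(1/tau)); multiplying both
    utilities by any c > 0 leaves P unchanged, so tau plays the same
    noise role as in the softmax but on log-utilities.
    """
    _check_positive(tau=tau, u_later=u_later, u_sooner=u_sooner)
    # Equivalent to a softmax on log-utilities, reuse its stability.
    return softmax_choice_prob(np.log(u_later), np.log(u_sooner), tau)


def choice_prob(spec: ModelSpec, V, T, sooner, k, tau, alpha=1.0, rho=1.0):
    """P(later) for offers (V at delay T vs ``sooner`` now) under ``spec``.

    ``rho`` scales the magnitudes of both options (it models the
    experienced size of rewards in a task context, not a bias toward one
    option).
    """
    u_later = utility(spec, V, T, k, alpha=alpha, rho=rho)
    u_sooner = utility(spec, sooner, 0.0, k, alpha=alpha, rho=rho)
    rule = softmax_choice_prob if spec.choice_rule == "softmax" else matching_choice_prob
    return rule(u_later, u_sooner, tau)


def trial_loglik(spec: ModelSpec, chose_later, V, T, sooner, k, tau, alpha=1.0, rho=1.0):
    """Per-trial Bernoulli log-likelihood log P(choice | params).

    Returns an array aligned with the inputs; summing gives the subject
    log-likelihood. Probabilities are clipped away from {0, 1}.
    """
    p = np.clip(choice_prob(spec, V, T, sooner, k, tau, alpha=alpha, rho=rho),
                _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    y = np.asarray(chose_later, float)
    return y * np.log(p) + (1.0 - y) * np.log1p(-p)


def convert_rate_units(k, from_unit: str, to_unit: str):
    """Re-express a discount rate (1/time) in another time unit.

    A rate per second becomes per day by multiplying by 86400 (the same
    kT product must describe the same offer). The induced shift of
    log(k) is ln of the unit ratio.
    """
    for u in (from_unit, to_unit):
        if u not in UNIT_SECONDS:
            raise ValueError(f"unknown delay unit: {u!r}")
    return np.asarray(k, float) * (UNIT_SECONDS[to_unit] / UNIT_SECONDS[from_unit])


def log_unit_shift(from_unit: str, to_unit: str) -> float:
    """ln of the time-unit ratio: the log(k) shift induced by re-expressing
    a rate from ``from_unit`` to ``to_unit`` (seconds->days: ln 86400 = 11.37)."""
    for u in (from_unit, to_unit):
        if u not in UNIT_SECONDS:
            raise ValueError(f"unknown delay unit: {u!r}")
    return float(np.log(UNIT_SECONDS[to_unit] / UNIT_SECONDS[from_unit]))


def magnitude_correction(k):
    """Magnitude-effect adjustment when moving a rate from the large-stake
    (long-horizon) reward scale to the small-stake (short-horizon) one:
    small rewards are discounted more steeply, so k doubles.

    Note this is a one-step cited adjustment, not an idempotent
    normalization: applying it twice quadruples k.
    """
    _check_positive(k=k)
    return np.asarray(k, float) * MAGNITUDE_EFFECT_FACTOR


def half_value_delay(logk):
    """Delay at which a delayed reward keeps exactly half its value.

    U = V/(1+kT) = V/2 exactly when kT = 1, so the half-value delay is
    1/k = exp(-logk), in the time unit of k.
    """
    return np.exp(-np.asarray(logk, float))


def orders_of_magnitude_gap(k_a, k_b) -> int:
    """floor(log10(k_a / k_b)) for two rates in the same units."""
    _check_positive(k_a=k_a, k_b=k_b)
    return int(np.floor(np.log10(float(k_a) / float(k_b))))
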