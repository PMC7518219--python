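"""Stochastic generators for sensory inputs and rewards, and the mean
motivation function.

Sensory inputs (visual balance ``u_b`` and complexity ``u_c``) are drawn
from a bivariate Gaussian truncated to the unit square. Rewards are the
sum of two independent components conditioned on the input: a linear
function of balance and an inverted-U (Gaussian bump) function of
complexity, each with additive untruncated Gaussian noise. Both mean
reward curves integrate to zero over [0, 1], so positive and negative
rewards occur in equal amounts. Motivation is deterministic given the
input (a mean-field treatment): a Gaussian-shaped function of complexity
bounded between ``m_min`` and ``m_max``.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy.special import erf

from .params import MotivationParams, RewardParams, SensoryParams

__all__ = [
    "SensorySample",
    "RewardSample",
    "DegenerateParametersError",
    "sample_sensory",
    "compute_phi",
    "mean_balance_reward",
    "sample_balance_reward",
    "mean_complexity_reward",
    "sample_complexity_reward",
    "mean_total_reward",
    "total_reward",
    "mean_motivation",
]


class SensorySample(NamedTuple):
    """One draw of (balance, complexity), both in [0, 1]."""

    u_b: float
    u_c: float


class RewardSample(NamedTuple):
    """One reward draw; ``r_star`` is exactly ``r_b + r_c``."""

    r_b: float
    r_c: float
    r_star: float


class DegenerateParametersError(RuntimeError):
    """Raised when the truncated input density has negligible mass in the
    unit square and rejection sampling exhausts its attempt budget."""


def sample_sensory(
    params: SensoryParams,
    n: int,
    rng: np.random.Generator,
    *,
    max_attempts_factor: int = 1000,
) -> np.ndarray:
    """Draw ``n`` i.i.d. samples from the truncated bivariate Gaussian.

    Sampling is by rejection from the untruncated Gaussian, which is
    exact for the renormalized-restriction definition of the truncation.
    At the standard parameters about 97% of proposals land inside the
    unit square. A budget of ``max_attempts_factor * n`` proposals guards
    against parameter sets that place negligible mass in the square.

    Returns an ``(n, 2)`` array with columns (u_b, u_c).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mean = params.mean
    cov = params.covariance
    out = np.empty((n, 2))
    filled = 0
    attempts = 0
    budget = max_attempts_factor * n
    while filled < n:
        batch = max(n - filled, 256)
        if attempts + batch > budget:
            batch = budget - attempts
            if batch <= 0:
                raise DegenerateParametersError(
                    "rejection budget exhausted: the input distribution has "
                    "negligible mass in the unit square"
                )
        draws = rng.multivariate_normal(mean, cov, size=batch)
        attempts += batch
        inside = draws[
            (draws[:, 0] >= 0.0)
            & (draws[:, 0] <= 1.0)
            & (draws[:, 1] >= 0.0)
            & (draws[:, 1] <= 1.0)
        ]
        take = min(len(inside), n - filled)
        out[filled : filled + take] = inside[:take]
        filled += take
    return out


def compute_phi(reward: RewardParams) -> float:
    """Offset making the mean complexity reward integrate to zero on [0, 1].

    The mean complexity reward is ``phi + beta*exp(-(u-gamma)^2/(2*theta^2))``;
    the bump's integral over [0, 1] is
    ``beta*theta*sqrt(pi/2) * (erf((1-gamma)/(sqrt(2)*theta)) + erf(gamma/(sqrt(2)*theta)))``
    and ``phi`` is its negative.
    """
    if reward.beta == 0:
        return 0.0
    s = math.sqrt(2.0) * reward.theta
    integral = (
        reward.beta
        * reward.theta
        * math.sqrt(math.pi / 2.0)
        * (erf((1.0 - reward.gamma) / s) + erf(reward.gamma / s))
    )
    return -float(integral)


def mean_balance_reward(u_b, alpha: float):
    """Mean balance reward ``-alpha + 2*alpha*u_b`` (zero-integral line)."""
    return -alpha + 2.0 * alpha * np.asarray(u_b, dtype=float)


def sample_balance_reward(u_b, reward: RewardParams, rng: np.random.Generator):
    """Balance reward draw: the mean line plus N(0, sigma_rb^2) noise."""
    mean = mean_balance_reward(u_b, reward.alpha)
    return mean + rng.normal(0.0, reward.sigma_rb, size=np.shape(mean))


def mean_complexity_reward(u_c, reward: RewardParams):
    """Mean complexity reward: zero-integral inverted-U in ``u_c``.

    With ``linear_complexity`` set, the bump is replaced by the same
    linear form as the balance reward (slope ``alpha``).
    """
    u_c = np.asarray(u_c, dtype=float)
    if reward.linear_complexity:
        return -reward.alpha + 2.0 * reward.alpha * u_c
    phi = compute_phi(reward)
    return phi + reward.beta * np.exp(
        -((u_c - reward.gamma) ** 2) / (2.0 * reward.theta**2)
    )


def sample_complexity_reward(u_c, reward: RewardParams, rng: np.random.Generator):
    """Complexity reward draw: the mean curve plus N(0, sigma_rc^2) noise."""
    mean = mean_complexity_reward(u_c, reward)
    return mean + rng.normal(0.0, reward.sigma_rc, size=np.shape(mean))


def mean_total_reward(u_b, u_c, reward: RewardParams):
    """Mean of the total reward r* at input (u_b, u_c)."""
    return mean_balance_reward(u_b, reward.alpha) + mean_complexity_reward(
        u_c, reward
    )


def total_reward(
    sensory: SensorySample, reward: RewardParams, rng: np.random.Generator
) -> RewardSample:
    """Draw both reward components independently given the input and sum.

    The draw order (balance first, then complexity) is fixed so runs are
    reproducible from the seed.
    """
    r_b = float(sample_balance_reward(sensory[0], reward, rng))
    r_c = float(sample_complexity_reward(sensory[1], reward, rng))
    return RewardSample(r_b=r_b, r_c=r_c, r_star=r_b + r_c)


def mean_motivation(u_c, motivation: MotivationParams):
    """Mean motivation at complexity ``u_c``.

    ``m_min + (m_max - m_min) * exp(-(u_c - mu_m)^2 / (2*sigma_m^2))`` —
    bounded in [m_min, m_max], maximal exactly at ``u_c = mu_m``, and
    independent of balance.
    """
    u_c = np.asarray(u_c, dtype=float)
    amp = motivation.m_max - motivation.m_min
    return motivation.m_min + amp * np.exp(
        -((u_c - motivation.mu_m) ** 2) / (2.0 * motivation.sigma_m**2)
    )
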