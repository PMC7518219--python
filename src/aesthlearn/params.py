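"""Typed parameter containers, validation, presets, and config-file I/O.

An individual learner is described by three parameter vectors:

* sensory statistics — a bivariate Gaussian over visual balance ``u_b``
  and visual complexity ``u_c``, truncated to the unit square;
* reward structure — reward rises linearly with balance and follows an
  inverted-U (Gaussian bump) in complexity, each with additive Gaussian
  noise and each constrained to integrate to zero over [0, 1];
* motivation — a Gaussian-shaped propensity to act, peaking at a
  preferred complexity, bounded between ``m_min`` and ``m_max``.

The weight-vector convention is fixed throughout the package:
index 0 is the balance weight, index 1 the complexity weight.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "SensoryParams",
    "RewardParams",
    "MotivationParams",
    "Individual",
    "LearningConfig",
    "standard_parameters",
    "validate",
    "individual_to_dict",
    "individual_from_dict",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class SensoryParams:
    """Parameters of the truncated bivariate Gaussian input distribution.

    Attributes
    ----------
    mu_b, mu_c : float
        Means of visual balance and complexity (of the untruncated
        Gaussian). Means outside [0, 1] are legal but trigger a warning,
        since samples themselves are confined to the unit square.
    sigma_ub, sigma_uc : float
        Standard deviations in the balance and complexity directions.
        Must be positive.
    rho : float
        Correlation between balance and complexity, strictly in (-1, 1).
    """

    mu_b: float
    mu_c: float
    sigma_ub: float
    sigma_uc: float
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_b <= 1.0) or not (0.0 <= self.mu_c <= 1.0):
            warnings.warn(
                "sensory means outside [0, 1]; samples are still truncated "
                "to the unit square",
                stacklevel=2,
            )

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_b, self.mu_c])

    @property
    def covariance(self) -> np.ndarray:
        off = self.rho * self.sigma_ub * self.sigma_uc
        return np.array(
            [[self.sigma_ub**2, off], [off, self.sigma_uc**2]]
        )


@dataclass(frozen=True)
class RewardParams:
    """Parameters of the stochastic reward structure.

    The mean balance reward is the line ``-alpha + 2*alpha*u_b``; the
    mean complexity reward is ``phi + beta*exp(-(u_c-gamma)^2/(2*theta^2))``
    where the offset ``phi`` is derived (not user-set) so that the mean
    integrates to zero over [0, 1]. Gaussian noise with standard
    deviations ``sigma_rb`` / ``sigma_rc`` is added to each component and
    is deliberately untruncated: rewards can be negative.

    ``linear_complexity`` replaces the complexity bump with the same
    linear form as balance (slope ``alpha``, noise ``sigma_rc``) — used
    by the "identical reward structures" ablation.
    """

    alpha: float
    sigma_rb: float
    beta: float
    gamma: float
    theta: float
    sigma_rc: float
    linear_complexity: bool = False


@dataclass(frozen=True)
class MotivationParams:
    """Parameters of the mean motivation function of complexity.

    ``m_bar(u_c) = m_min + (m_max - m_min) * exp(-(u_c - mu_m)^2 / (2*sigma_m^2))``

    with 0 <= m_min <= m_max <= 1; ``mu_m`` is the complexity of peak
    motivation and ``sigma_m`` its width. Motivation is modelled as
    independent of balance.
    """

    m_min: float
    m_max: float
    mu_m: float
    sigma_m: float


@dataclass(frozen=True)
class Individual:
    """A full parameterization of one learner.

    ``background_label`` is a free-form tag for the social/environmental
    background the parameters are meant to represent; it carries no
    computational meaning (population-level sampling of individuals is
    out of scope).
    """

    sensory: SensoryParams
    reward: RewardParams
    motivation: MotivationParams
    background_label: str = ""


@dataclass(frozen=True)
class LearningConfig:
    """Controls for one simulated learning run.

    Attributes
    ----------
    w0 : (float, float)
        Initial (balance, complexity) weights.
    epsilon : float
        Learning step of the discretized delta rule (> 0). With the unit
        time step used throughout, this equals the continuous-time
        learning-rate constant.
    n_steps : int
        Number of weight updates.
    seed : int
        Seed for the single RNG stream driving all stochastic draws.
    record_start, record_stride : int
        Trajectory rows are kept for step indices
        ``record_start, record_start + record_stride, ...`` up to
        ``n_steps``. The defaults (0, 1) record every step including the
        initial weights.
    motivation_mode : str
        ``"mean_field"`` (motivation follows the individual's mean
        motivation function of the sampled complexity) or
        ``"constant:<c>"`` for a fixed motivation ``c`` in [0, 1].
    """

    w0: tuple[float, float] = (0.0, 0.0)
    epsilon: float = 0.01
    n_steps: int = 30_000
    seed: int = 0
    record_start: int = 0
    record_stride: int = 1
    motivation_mode: str = "mean_field"

    def constant_motivation(self) -> float | None:
        """The fixed motivation level, or None in mean-field mode."""
        if self.motivation_mode == "mean_field":
            return None
        if self.motivation_mode.startswith("constant:"):
            return float(self.motivation_mode.split(":", 1)[1])
        raise ValueError(f"unknown motivation_mode {self.motivation_mode!r}")

    def check(self) -> None:
        """Raise ValueError on an invalid configuration."""
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.record_start < 0 or self.record_stride < 1:
            raise ValueError("record_start >= 0 and record_stride >= 1 required")
        c = self.constant_motivation()  # validates the mode string
        if c is not None and not (0.0 <= c <= 1.0):
            raise ValueError("constant motivation must lie in [0, 1]")


def standard_parameters() -> tuple[Individual, LearningConfig]:
    """The standard parameter set used throughout the shipped experiments.

    Sensory [mu_b, mu_c, sigma_ub, sigma_uc, rho] = [0.5, 0.5, 0.2, 0.2, -0.5];
    reward [alpha, sigma_rb, beta, gamma, theta, sigma_rc] =
    [0.6, 0.1, 1, 0.75, 0.1, 0.1]; motivation [m_min, m_max, mu_m, sigma_m] =
    [0.1, 0.6, 0.65, 0.1]; weights start at [0, 0] with step 0.01.
    """
    individual = Individual(
        sensory=SensoryParams(0.5, 0.5, 0.2, 0.2, -0.5),
        reward=RewardParams(0.6, 0.1, 1.0, 0.75, 0.1, 0.1),
        motivation=MotivationParams(0.1, 0.6, 0.65, 0.1),
        background_label="standard",
    )
    config = LearningConfig()
    return individual, config


def validate(individual: Individual) -> list[str]:
    """Return a list of invariant violations (empty when valid).

    Each entry names the offending field and the violated bound. The
    containers themselves never raise, so invalid parameter sets can be
    constructed, inspected and reported on.
    """
    s, r, m = individual.sensory, individual.reward, individual.motivation
    out: list[str] = []
    if not s.sigma_ub > 0:
        out.append(f"sigma_ub must be > 0 (got {s.sigma_ub})")
    if not s.sigma_uc > 0:
        out.append(f"sigma_uc must be > 0 (got {s.sigma_uc})")
    if not (-1.0 < s.rho < 1.0):
        out.append(f"rho must satisfy -1 < rho < 1 (got {s.rho})")
    for name in ("alpha", "sigma_rb", "beta", "theta", "sigma_rc"):
        val = getattr(r, name)
        if not val > 0:
            out.append(f"{name} must be > 0 (got {val})")
    if not (0.0 <= r.gamma <= 1.0):
        out.append(f"gamma must lie in [0, 1] (got {r.gamma})")
    if not (0.0 <= m.m_min <= 1.0):
        out.append(f"m_min must lie in [0, 1] (got {m.m_min})")
    if not (0.0 <= m.m_max <= 1.0):
        out.append(f"m_max must lie in [0, 1] (got {m.m_max})")
    if m.m_min > m.m_max:
        out.append(
            f"m_min must be <= m_max (got m_min={m.m_min}, m_max={m.m_max})"
        )
    if not (0.0 <= m.mu_m <= 1.0):
        out.append(f"mu_m must lie in [0, 1] (got {m.mu_m})")
    if not m.sigma_m > 0:
        out.append(f"sigma_m must be > 0 (got {m.sigma_m})")
    return out


# ---------------------------------------------------------------------------
# Config-file round trip (YAML). Sections mirror the parameter vectors in
# their conventional order; the learning section mirrors LearningConfig.

def individual_to_dict(individual: Individual) -> dict:
    return {
        "sensory": dataclasses.asdict(individual.sensory),
        "reward": dataclasses.asdict(individual.reward),
        "motivation": dataclasses.asdict(individual.motivation),
        "background_label": individual.background_label,
    }


def individual_from_dict(d: dict) -> Individual:
    return Individual(
        sensory=SensoryParams(**d["sensory"]),
        reward=RewardParams(**d["reward"]),
        motivation=MotivationParams(**d["motivation"]),
        background_label=d.get("background_label", ""),
    )


def save_config(individual: Individual, config: LearningConfig, path) -> None:
    """Write a YAML config with sensory/reward/motivation/learning sections."""
    doc = individual_to_dict(individual)
    learning = dataclasses.asdict(config)
    learning["w0"] = list(config.w0)
    doc["learning"] = learning
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[Individual, LearningConfig]:
    """Read a YAML config written by :func:`save_config` (or hand-edited)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    individual = individual_from_dict(doc)
    learning = dict(doc.get("learning", {}))
    if "w0" in learning:
        learning["w0"] = tuple(float(x) for x in learning["w0"])
    config = LearningConfig(**learning)
    return individual, config
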