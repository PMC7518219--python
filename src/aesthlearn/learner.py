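"""The motivation-gated delta-rule learning loop.

The learner maintains a weight pair ``w = (w_b, w_c)`` linking the
sensory input ``u = (u_b, u_c)`` to a predicted reward ("aesthetic
value") ``v = m_bar * (w . u)``. On each step a fresh input, reward and
motivation are drawn and the weights move along the discretized delta
rule

    w'  =  w + epsilon * m_bar * (r_star - w . u) * u

so that motivation gates the effective learning rate: with ``m_bar = 0``
learning freezes. The per-step prediction error recorded in trajectories
is ``delta = m_bar * (r_star - w . u)``, i.e. received minus predicted
reward with motivation applied to both.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .environment import (
    mean_balance_reward,
    mean_complexity_reward,
    mean_motivation,
    sample_sensory,
)
from .params import Individual, LearningConfig

__all__ = ["Trajectory", "value", "update_step", "run_simulation"]

# Abort threshold for runaway weights (signals a step size too large for
# the reward scale).
_DIVERGENCE_BOUND = 1e6


@dataclass
class Trajectory:
    """Recorded time series of one learning run.

    Arrays share a common length. Row ``i`` describes the state at step
    index ``step[i]``: ``w[i]`` are the weights *after* that step's
    update, while ``u``, ``r_star``, ``m_bar``, ``delta`` and ``v``
    describe the sample consumed by that update (value and prediction
    error are evaluated at the pre-update weights). The row for step 0,
    when recorded, holds the initial weights and NaN sample fields.
    """

    step: np.ndarray
    w: np.ndarray
    u: np.ndarray
    r_star: np.ndarray
    m_bar: np.ndarray
    delta: np.ndarray
    v: np.ndarray
    individual: Individual | None = None
    config: LearningConfig | None = None

    def __len__(self) -> int:
        return len(self.step)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "w_b": self.w[:, 0],
                "w_c": self.w[:, 1],
                "u_b": self.u[:, 0],
                "u_c": self.u[:, 1],
                "r_star": self.r_star,
                "m_bar": self.m_bar,
                "delta": self.delta,
                "v": self.v,
            }
        )

    def manifest(self) -> dict:
        """Provenance sufficient to re-run this trajectory bit-identically."""
        from .params import individual_to_dict

        out: dict = {"version": __version__}
        if self.individual is not None:
            out["individual"] = individual_to_dict(self.individual)
        if self.config is not None:
            cfg = dataclasses.asdict(self.config)
            cfg["w0"] = list(self.config.w0)
            out["config"] = cfg
        return out

    def to_csv(self, path, *, sidecar: bool = True) -> None:
        """Write the trajectory as CSV plus a JSON provenance sidecar."""
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.manifest(), fh, indent=2, sort_keys=True)


def value(w, u, m_bar: float) -> float:
    """Aesthetic value ``v = m_bar * (w . u)`` of input ``u`` under weights ``w``."""
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    return float(m_bar * (w @ u))


def update_step(w, u, r_star: float, m_bar: float, epsilon: float) -> np.ndarray:
    """One delta-rule update: ``w + epsilon*m_bar*(r_star - w.u)*u``."""
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    return w + epsilon * m_bar * (r_star - w @ u) * u


def run_simulation(
    individual: Individual,
    config: LearningConfig,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run the full stochastic learning loop and record a trajectory.

    Each step draws a sensory sample from the truncated bivariate
    Gaussian, a balance reward and a complexity reward conditioned on
    it, evaluates the motivation (mean-field in ``u_c``, or the constant
    from ``config.motivation_mode``), and applies the delta-rule update.

    A single RNG stream drives everything; for speed the stream is
    consumed in blocks — all sensory samples first, then all balance
    reward noise, then all complexity reward noise — rather than
    interleaved per step. Trajectories are bit-reproducible from
    ``config.seed`` (used when ``rng`` is not supplied).
    """
    config.check()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_steps

    if n == 0:
        w0 = np.asarray(config.w0, dtype=float)
        nan = np.full(1, np.nan)
        return Trajectory(
            step=np.zeros(1, dtype=int),
            w=w0[None, :].copy(),
            u=np.full((1, 2), np.nan),
            r_star=nan.copy(),
            m_bar=nan.copy(),
            delta=nan.copy(),
            v=nan.copy(),
            individual=individual,
            config=config,
        )

    u = sample_sensory(individual.sensory, n, rng)
    r_b = mean_balance_reward(u[:, 0], individual.reward.alpha) + rng.normal(
        0.0, individual.reward.sigma_rb, size=n
    )
    r_c = mean_complexity_reward(u[:, 1], individual.reward) + rng.normal(
        0.0, individual.reward.sigma_rc, size=n
    )
    r_star = r_b + r_c

    const_m = config.constant_motivation()
    if const_m is None:
        m = np.asarray(mean_motivation(u[:, 1], individual.motivation))
    else:
        m = np.full(n, const_m)

    # Scalar recursion in plain floats: ~30k steps run in milliseconds.
    ub_l = u[:, 0].tolist()
    uc_l = u[:, 1].tolist()
    rs_l = r_star.tolist()
    m_l = m.tolist()
    eps = config.epsilon

    w_b, w_c = float(config.w0[0]), float(config.w0[1])
    wb_arr = np.empty(n + 1)
    wc_arr = np.empty(n + 1)
    v_arr = np.empty(n + 1)
    d_arr = np.empty(n + 1)
    wb_arr[0], wc_arr[0] = w_b, w_c
    v_arr[0] = np.nan
    d_arr[0] = np.nan

    for k in range(n):
        ub, uc, mk, rk = ub_l[k], uc_l[k], m_l[k], rs_l[k]
        wu = w_b * ub + w_c * uc
        v_arr[k + 1] = mk * wu
        resid = rk - wu
        d_arr[k + 1] = mk * resid
        g = eps * mk * resid
        w_b += g * ub
        w_c += g * uc
        if not (-_DIVERGENCE_BOUND < w_b < _DIVERGENCE_BOUND) or not (
            -_DIVERGENCE_BOUND < w_c < _DIVERGENCE_BOUND
        ):
            raise FloatingPointError(
                f"weights diverged at step {k + 1} "
                f"(w=({w_b:.3g}, {w_c:.3g})); epsilon={eps} is likely too "
                "large for this reward scale"
            )
        wb_arr[k + 1] = w_b
        wc_arr[k + 1] = w_c

    idx = np.arange(config.record_start, n + 1, config.record_stride)
    u_full = np.vstack([np.full((1, 2), np.nan), u])
    r_full = np.concatenate([[np.nan], r_star])
    m_full = np.concatenate([[np.nan], m])

    return Trajectory(
        step=idx,
        w=np.column_stack([wb_arr[idx], wc_arr[idx]]),
        u=u_full[idx],
        r_star=r_full[idx],
        m_bar=m_full[idx],
        delta=d_arr[idx],
        v=v_arr[idx],
        individual=individual,
        config=config,
    )
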