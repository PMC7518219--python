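"""Equilibrium and landscape analysis.

The learning loop performs stochastic gradient descent on the
motivation-weighted expected squared prediction error

    E(w) = < (r - v)^2 / m >  =  E_u[ m_bar(u) * ( (rbar*(u) - w.u)^2
                                                  + sigma_rb^2 + sigma_rc^2 ) ]

where the expectation is over the truncated input density (the division
by ``m`` cancels one motivation factor because ``r - v = m*(r* - w.u)``).
E is a positive quadratic form in ``w``,

    E(w) = w' A w - 2 b' w + c,
    A = E_u[m_bar * u u'],   b = E_u[m_bar * rbar* * u],

so its unique minimizer — the fixed point the stochastic weights hover
around — is ``w* = A^-1 b``. All moments are computed by a Gauss-Legendre
product rule on the unit square; a Monte-Carlo estimator of E is provided
as an independent cross-check.

This module also provides the per-sample solution hyperplane (all weight
pairs producing the same value for one sample), value landscapes over the
input space with peak-shift diagnostics, and the late-window competition
metrics used to quantify weight divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .environment import mean_motivation, mean_total_reward, sample_sensory
from .learner import Trajectory
from .params import Individual, MotivationParams

__all__ = [
    "FixedPoint",
    "ErrorSurface",
    "ValueLandscape",
    "DegenerateAnalysisError",
    "expected_error",
    "expected_error_mc",
    "fixed_point",
    "hyperplane",
    "hyperplane_distance",
    "value_landscape",
    "value_timecourse",
    "competition_metrics",
    "error_surface",
]

#: Default Gauss-Legendre order per axis. The complexity-reward bump has
#: width theta = 0.1 at the standard parameters, so the rule needs fine
#: resolution; convergence is verified by order doubling in the tests.
DEFAULT_QUAD_ORDER = 80


class DegenerateAnalysisError(RuntimeError):
    """Raised when the analysis problem is degenerate (no input mass in
    the unit square, or a singular second-moment matrix, e.g. motivation
    identically zero)."""


@lru_cache(maxsize=8)
def _gl_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped from [-1, 1] to [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(order)
    return (x + 1.0) / 2.0, w / 2.0


def _quad_grid(individual: Individual, order: int):
    """Quadrature nodes, combined weights, and the normalized truncated
    input density evaluated on the product grid.

    Returns (ub, uc, wts) flattened, where ``wts`` already includes the
    density, so ``sum(wts * f(ub, uc))`` approximates E_u[f].
    """
    x, w = _gl_nodes(order)
    UB, UC = np.meshgrid(x, x, indexing="ij")
    W2 = np.outer(w, w)
    ub, uc, w2 = UB.ravel(), UC.ravel(), W2.ravel()
    pts = np.column_stack([ub, uc])
    g2 = multivariate_normal.pdf(
        pts, mean=individual.sensory.mean, cov=individual.sensory.covariance
    )
    mass = float(np.sum(w2 * g2))
    if not np.isfinite(mass) or mass <= 1e-300:
        raise DegenerateAnalysisError(
            "input density has negligible mass in the unit square"
        )
    return ub, uc, w2 * g2 / mass


@lru_cache(maxsize=64)
def _error_moments(
    individual: Individual, order: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """(A, b, c) of the quadratic error form under the truncated density.

    Cached on the (hashable, frozen) individual; callers must treat the
    returned arrays as read-only.
    """
    ub, uc, wts = _quad_grid(individual, order)
    m = np.asarray(mean_motivation(uc, individual.motivation))
    rbar = np.asarray(mean_total_reward(ub, uc, individual.reward))
    wm = wts * m
    A = np.array(
        [
            [np.sum(wm * ub * ub), np.sum(wm * ub * uc)],
            [np.sum(wm * ub * uc), np.sum(wm * uc * uc)],
        ]
    )
    b = np.array([np.sum(wm * rbar * ub), np.sum(wm * rbar * uc)])
    noise_var = individual.reward.sigma_rb**2 + individual.reward.sigma_rc**2
    c = float(np.sum(wm * rbar**2) + noise_var * np.sum(wm))
    return A, b, c


@dataclass
class FixedPoint:
    """Minimizer of the expected error with its defining matrices.

    ``A w* = b`` holds to quadrature tolerance; ``condition`` is the
    eigenvalue ratio of A (the anisotropy of the error bowl).
    """

    w_star: np.ndarray
    A: np.ndarray
    b: np.ndarray
    condition: float


@dataclass
class ErrorSurface:
    """Expected error on a weight grid.

    ``E[i, j]`` is the error at ``(w_b[i], w_c[j])``. ``anisotropy`` is
    the eigenvalue ratio of the curvature matrix A and
    ``principal_directions`` its eigenvectors (columns, ascending
    eigenvalue — the first column is the shallow "hammock" axis).
    """

    w_b: np.ndarray
    w_c: np.ndarray
    E: np.ndarray
    method: str
    n_points: int
    anisotropy: float
    principal_directions: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        WB, WC = np.meshgrid(self.w_b, self.w_c, indexing="ij")
        return pd.DataFrame(
            {"w_b": WB.ravel(), "w_c": WC.ravel(), "E": self.E.ravel()}
        )


@dataclass
class ValueLandscape:
    """Value ``V(u) = m_bar(u_c) * (w . u)`` on a grid over the unit square,
    with the input-density mode and the location of the value maximum —
    their mismatch is the peak-shift (value exaggeration) diagnostic."""

    u_b: np.ndarray
    u_c: np.ndarray
    V: np.ndarray
    w: np.ndarray
    motivation: MotivationParams
    density_mode: tuple[float, float]
    argmax: tuple[float, float]
    v_at_mode: float
    v_max: float

    def to_dataframe(self) -> pd.DataFrame:
        UB, UC = np.meshgrid(self.u_b, self.u_c, indexing="ij")
        return pd.DataFrame(
            {"u_b": UB.ravel(), "u_c": UC.ravel(), "V": self.V.ravel()}
        )


def expected_error(
    w, individual: Individual, order: int = DEFAULT_QUAD_ORDER
) -> float:
    """Expected motivation-weighted squared prediction error at weights ``w``.

    Undefined (raises) when motivation is identically zero, since the
    defining time average conditions on motivated steps.
    """
    if (
        individual.motivation.m_max == 0.0
        and individual.motivation.m_min == 0.0
    ):
        raise DegenerateAnalysisError(
            "expected error is undefined for motivation identically zero"
        )
    w = np.asarray(w, dtype=float)
    A, b, c = _error_moments(individual, order)
    return float(w @ A @ w - 2.0 * b @ w + c)


def expected_error_mc(
    w,
    individual: Individual,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the expected error and its standard error.

    Uses the exact per-sample integrand
    ``m_bar * ((rbar* - w.u)^2 + noise variance)`` over sensory draws —
    an estimator independent of the quadrature path.
    """
    w = np.asarray(w, dtype=float)
    u = sample_sensory(individual.sensory, n_samples, rng)
    m = np.asarray(mean_motivation(u[:, 1], individual.motivation))
    rbar = np.asarray(mean_total_reward(u[:, 0], u[:, 1], individual.reward))
    noise_var = individual.reward.sigma_rb**2 + individual.reward.sigma_rc**2
    vals = m * ((rbar - u @ w) ** 2 + noise_var)
    est = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(n_samples))
    return est, se


def fixed_point(
    individual: Individual, order: int = DEFAULT_QUAD_ORDER
) -> FixedPoint:
    """Closed-form minimizer ``w* = A^-1 b`` of the expected error."""
    A, b, _ = _error_moments(individual, order)
    evals = np.linalg.eigvalsh(A)
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise DegenerateAnalysisError(
            "second-moment matrix A is singular (motivation or input "
            "distribution degenerate)"
        )
    w_star = np.linalg.solve(A, b)
    return FixedPoint(
        w_star=w_star, A=A, b=b, condition=float(evals[1] / evals[0])
    )


def hyperplane(u, m_bar: float, v_target: float):
    """Coefficients of the solution hyperplane ``a . w = v_target``.

    All weight pairs on the hyperplane produce the same value
    ``v_target`` for the sample ``(u, m_bar)``; the coefficients are
    ``a_i = m_bar * u_i``. Returns ``(a, v_target)``.
    """
    a = m_bar * np.asarray(u, dtype=float)
    return a, float(v_target)


def hyperplane_distance(w, u, m_bar: float, v_target: float) -> float:
    """Signed Euclidean distance from ``w`` to the solution hyperplane.

    Positive when the target value exceeds the value produced by ``w``.
    Undefined (raises) when ``m_bar = 0`` or ``u = 0``, since then every
    weight pair produces value zero and no hyperplane exists.
    """
    a, v_target = hyperplane(u, m_bar, v_target)
    norm = float(np.linalg.norm(a))
    if norm == 0.0:
        raise ValueError(
            "hyperplane distance undefined: m_bar = 0 or u = 0 gives a "
            "degenerate (all-of-weight-space) solution set"
        )
    w = np.asarray(w, dtype=float)
    return float((v_target - a @ w) / norm)


def value_landscape(
    w,
    motivation: MotivationParams,
    grid_resolution: int = 101,
    density_mode: tuple[float, float] = (0.5, 0.5),
) -> ValueLandscape:
    """Value ``V(u)`` on a uniform grid over the unit square.

    ``density_mode`` is the most probable input (for a truncated
    Gaussian with interior mean this is the mean itself); the landscape
    reports V there and at the grid argmax so peak shift can be read off
    directly.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    w = np.asarray(w, dtype=float)
    g = np.linspace(0.0, 1.0, grid_resolution)
    UB, UC = np.meshgrid(g, g, indexing="ij")
    m = np.asarray(mean_motivation(UC, motivation))
    V = m * (w[0] * UB + w[1] * UC)
    i, j = np.unravel_index(np.argmax(V), V.shape)
    mb = float(mean_motivation(density_mode[1], motivation))
    v_mode = mb * float(w @ np.asarray(density_mode))
    return ValueLandscape(
        u_b=g,
        u_c=g,
        V=V,
        w=w,
        motivation=motivation,
        density_mode=tuple(density_mode),
        argmax=(float(g[i]), float(g[j])),
        v_at_mode=v_mode,
        v_max=float(V[i, j]),
    )


def value_timecourse(
    trajectory: Trajectory, probes, motivation: MotivationParams
) -> pd.DataFrame:
    """Value of each probe input at every recorded step.

    ``probes`` is a sequence of (u_b, u_c) points in the unit square.
    Returns a DataFrame with a ``step`` column and one ``V_i`` column per
    probe, ``V_i(t) = m_bar(probe_c) * (w(t) . probe)``.
    """
    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    if np.any(probes < 0.0) or np.any(probes > 1.0):
        raise ValueError("probes must lie in the unit square")
    m = np.asarray(mean_motivation(probes[:, 1], motivation))
    V = (trajectory.w @ probes.T) * m[None, :]
    out = {"step": trajectory.step}
    for i in range(probes.shape[0]):
        out[f"V_{i}"] = V[:, i]
    return pd.DataFrame(out)


def competition_metrics(
    trajectory: Trajectory, late_fraction: float = 1.0 / 3.0
) -> dict:
    """Late-window summary of apparent competition between the weights.

    Over the last ``late_fraction`` of recorded steps, reports the mean
    balance and complexity weights, their difference
    ``separation = mean(w_c) - mean(w_b)`` (positive when complexity has
    won), and the Pearson correlation of per-step weight increments
    (negative when the weights move in opposition).
    """
    n = len(trajectory)
    n_late = max(int(round(n * late_fraction)), 2)
    if n_late > n:
        raise ValueError("late window longer than trajectory")
    w_late = trajectory.w[n - n_late :]
    mean_b = float(np.mean(w_late[:, 0]))
    mean_c = float(np.mean(w_late[:, 1]))
    dw = np.diff(w_late, axis=0)
    sd = dw.std(axis=0)
    if np.all(sd > 0):
        corr = float(np.corrcoef(dw[:, 0], dw[:, 1])[0, 1])
    else:
        corr = float("nan")  # frozen learner: increments identically zero
    return {
        "late_mean_w_b": mean_b,
        "late_mean_w_c": mean_c,
        "separation": mean_c - mean_b,
        "increment_correlation": corr,
    }


def error_surface(
    individual: Individual,
    w_b_grid,
    w_c_grid,
    order: int = DEFAULT_QUAD_ORDER,
) -> ErrorSurface:
    """Expected error over a weight grid, with the anisotropy of the bowl.

    The anisotropy (eigenvalue ratio of A) quantifies the hammock shape:
    1 for an isotropic bowl, larger when one weight direction is much
    stiffer than the other.
    """
    w_b_grid = np.asarray(w_b_grid, dtype=float)
    w_c_grid = np.asarray(w_c_grid, dtype=float)
    A, b, c = _error_moments(individual, order)
    WB, WC = np.meshgrid(w_b_grid, w_c_grid, indexing="ij")
    E = (
        A[0, 0] * WB**2
        + 2.0 * A[0, 1] * WB * WC
        + A[1, 1] * WC**2
        - 2.0 * (b[0] * WB + b[1] * WC)
        + c
    )
    evals, evecs = np.linalg.eigh(A)
    if evals[0] <= 0:
        raise DegenerateAnalysisError("curvature matrix A is not positive definite")
    return ErrorSurface(
        w_b=w_b_grid,
        w_c=w_c_grid,
        E=E,
        method="quadrature",
        n_points=order * order,
        anisotropy=float(evals[1] / evals[0]),
        principal_directions=evecs,
    )
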