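import dataclasses

import numpy as np
import pytest

from aesthlearn.analysis import (
    DegenerateAnalysisError,
    competition_metrics,
    error_surface,
    expected_error,
    expected_error_mc,
    fixed_point,
    hyperplane,
    hyperplane_distance,
    value_landscape,
    value_timecourse,
)
from aesthlearn.environment import mean_motivation
from aesthlearn.learner import run_simulation, update_step
from aesthlearn.params import (
    Individual,
    MotivationParams,
    RewardParams,
    SensoryParams,
)


def _exchange_symmetric_individual():
    """Constant motivation, identical linear rewards, symmetric inputs:
    invariant under swapping the balance and complexity coordinates."""
    return Individual(
        sensory=SensoryParams(0.5, 0.5, 0.2, 0.2, -0.5),
        reward=RewardParams(0.6, 0.1, 1.0, 0.75, 0.1, 0.1, linear_complexity=True),
        motivation=MotivationParams(1.0, 1.0, 0.65, 0.1),
    )


# ---------------------------------------------------------------------------
# fixed point

def test_fixed_point_zero_mean_rewards_gives_zero_weights(standard):
    individual, _ = standard
    silent = dataclasses.replace(
        individual,
        reward=RewardParams(0.0, 0.1, 0.0, 0.75, 0.1, 0.1),
    )
    fp = fixed_point(silent)
    assert np.allclose(fp.w_star, [0.0, 0.0], atol=1e-14)


def test_fixed_point_exchange_symmetry_gives_equal_components():
    fp = fixed_point(_exchange_symmetric_individual())
    assert fp.w_star[0] == pytest.approx(fp.w_star[1], abs=1e-10)
    assert fp.A[0, 0] == pytest.approx(fp.A[1, 1], abs=1e-12)


def test_fixed_point_standard_favors_complexity(standard):
    individual, _ = standard
    fp = fixed_point(individual)
    assert fp.w_star[1] > fp.w_star[0] > 0.0
    assert np.allclose(fp.A @ fp.w_star, fp.b, atol=1e-12)
    assert fp.condition > 1.0
    # A symmetric positive definite
    assert np.allclose(fp.A, fp.A.T)
    assert np.all(np.linalg.eigvalsh(fp.A) > 0)


def test_fixed_point_is_quadrature_converged(standard):
    individual, _ = standard
    w60 = fixed_point(individual, order=60).w_star
    w120 = fixed_point(individual, order=120).w_star
    assert np.allclose(w60, w120, atol=1e-10)


def test_fixed_point_degenerate_motivation_raises(standard):
    individual, _ = standard
    dead = dataclasses.replace(
        individual, motivation=MotivationParams(0.0, 0.0, 0.65, 0.1)
    )
    with pytest.raises(DegenerateAnalysisError):
        fixed_point(dead)


# ---------------------------------------------------------------------------
# expected error

def test_expected_error_is_convex_around_fixed_point(standard):
    individual, _ = standard
    fp = fixed_point(individual)
    e_star = expected_error(fp.w_star, individual)
    assert e_star > 0.0  # linear model cannot absorb noise + bump mismatch
    for angle in np.linspace(0, 2 * np.pi, 8, endpoint=False):
        d = 0.3 * np.array([np.cos(angle), np.sin(angle)])
        assert expected_error(fp.w_star + d, individual) > e_star


def test_expected_error_matches_monte_carlo(standard, rng):
    individual, _ = standard
    e_quad = expected_error([0.0, 0.0], individual)
    est, se = expected_error_mc([0.0, 0.0], individual, 300_000, rng)
    assert abs(est - e_quad) < 3.0 * se


def test_expected_error_undefined_for_zero_motivation(standard):
    individual, _ = standard
    dead = dataclasses.replace(
        individual, motivation=MotivationParams(0.0, 0.0, 0.65, 0.1)
    )
    with pytest.raises(DegenerateAnalysisError):
        expected_error([0.0, 0.0], dead)


# ---------------------------------------------------------------------------
# hyperplane geometry

def test_hyperplane_coefficients_and_zero_distance():
    a, v = hyperplane([0.5, 0.25], 0.6, 0.3)
    assert np.allclose(a, [0.3, 0.15])
    w_on = np.array([1.0, 0.0])  # a.w = 0.3 = v
    assert hyperplane_distance(w_on, [0.5, 0.25], 0.6, 0.3) == pytest.approx(
        0.0, abs=1e-15
    )


def test_update_moves_toward_sample_hyperplane(rng):
    """Each delta-rule step shrinks the distance to the hyperplane of
    weights that would reproduce the sample's value exactly."""
    for _ in range(100):
        w = rng.normal(size=2)
        u = rng.uniform(0.05, 1.0, size=2)
        m = rng.uniform(0.1, 1.0)
        r = rng.normal()
        v_target = m * r
        d0 = hyperplane_distance(w, u, m, v_target)
        w1 = update_step(w, u, r, m, 0.01)
        d1 = hyperplane_distance(w1, u, m, v_target)
        assert abs(d1) <= abs(d0) + 1e-12


def test_weight_redundancy_same_value_on_hyperplane():
    """Distinct weight pairs with equal a.w produce identical value."""
    u, m = np.array([0.5, 0.25]), 0.6
    w1 = np.array([1.0, 0.0])
    w2 = np.array([0.0, 2.0])  # both give w.u = 0.5
    assert w1 @ u == w2 @ u
    assert m * (w1 @ u) == m * (w2 @ u)


def test_hyperplane_distance_undefined_without_motivation():
    with pytest.raises(ValueError):
        hyperplane_distance([1.0, 1.0], [0.5, 0.5], 0.0, 0.3)


# ---------------------------------------------------------------------------
# landscapes

def test_value_landscape_zero_weights_is_flat(standard):
    individual, _ = standard
    scape = value_landscape([0.0, 0.0], individual.motivation)
    assert np.all(scape.V == 0.0)


def test_value_landscape_linear_case_peaks_on_edge():
    m = MotivationParams(1.0, 1.0, 0.5, 0.1)
    scape = value_landscape([1.0, 0.0], m, grid_resolution=51)
    UB = scape.u_b[:, None] * np.ones_like(scape.u_c)[None, :]
    assert np.allclose(scape.V, UB)
    assert scape.argmax[0] == 1.0


def test_value_exaggeration_at_fixed_point(standard):
    """The learned value peaks away from the most probable input and
    exceeds the value there: the peak-shift effect."""
    individual, _ = standard
    fp = fixed_point(individual)
    scape = value_landscape(fp.w_star, individual.motivation)
    assert scape.argmax != scape.density_mode
    assert scape.v_max > scape.v_at_mode
    # exaggeration toward high balance and high complexity
    assert scape.argmax[0] > 0.5 and scape.argmax[1] > 0.5


def test_value_timecourse_probes(standard_trajectory):
    individual = standard_trajectory.individual
    probes = [(0.5, 0.5), (0.75, 0.75), (0.25, 0.25)]
    tc = value_timecourse(standard_trajectory, probes, individual.motivation)
    # zero initial weights: all probe values start at 0
    assert np.allclose(tc.iloc[0][["V_0", "V_1", "V_2"]], 0.0)
    # Cauchy-Schwarz bound per probe
    for i, p in enumerate(probes):
        m_p = float(mean_motivation(p[1], individual.motivation))
        bound = m_p * np.linalg.norm(standard_trajectory.w, axis=1) * np.linalg.norm(p)
        assert np.all(np.abs(tc[f"V_{i}"].to_numpy()) <= bound + 1e-12)
    # late-time ordering matches the fixed-point prediction
    fp = fixed_point(individual)
    pred = [
        float(mean_motivation(p[1], individual.motivation)) * (fp.w_star @ p)
        for p in probes
    ]
    late = tc.iloc[-2000:][["V_0", "V_1", "V_2"]].mean().to_numpy()
    assert list(np.argsort(late)) == list(np.argsort(pred))


def test_value_timecourse_rejects_out_of_range_probes(standard_trajectory):
    with pytest.raises(ValueError):
        value_timecourse(
            standard_trajectory, [(1.5, 0.5)], standard_trajectory.individual.motivation
        )


# ---------------------------------------------------------------------------
# competition metrics and error surface

def test_competition_metrics_frozen_learner(standard):
    individual, config = standard
    config = dataclasses.replace(
        config, motivation_mode="constant:0", n_steps=300, w0=(0.1, 0.45)
    )
    traj = run_simulation(individual, config)
    m = competition_metrics(traj)
    assert m["separation"] == pytest.approx(0.45 - 0.1, abs=1e-15)
    assert np.isnan(m["increment_correlation"])


def test_competition_metrics_standard_run(standard_trajectory):
    m = competition_metrics(standard_trajectory)
    assert m["separation"] > 0.0
    assert m["late_mean_w_c"] > m["late_mean_w_b"]


def test_competition_metrics_window_validation(standard_trajectory):
    with pytest.raises(ValueError):
        competition_metrics(standard_trajectory, late_fraction=2.0)


def test_error_surface_minimum_matches_fixed_point(standard):
    individual, _ = standard
    fp = fixed_point(individual)
    grid_b = np.linspace(fp.w_star[0] - 0.4, fp.w_star[0] + 0.4, 81)
    grid_c = np.linspace(fp.w_star[1] - 0.4, fp.w_star[1] + 0.4, 81)
    surf = error_surface(individual, grid_b, grid_c)
    i, j = np.unravel_index(np.argmin(surf.E), surf.E.shape)
    cell = grid_b[1] - grid_b[0]
    assert abs(grid_b[i] - fp.w_star[0]) <= cell
    assert abs(grid_c[j] - fp.w_star[1]) <= cell
    assert surf.anisotropy > 1.0
    assert np.all(surf.E >= 0.0)


def test_error_surface_exchange_symmetry_principal_directions():
    """For an exchange-symmetric setup the hammock's principal axes are
    exactly the diagonal and antidiagonal of weight space."""
    surf = error_surface(
        _exchange_symmetric_individual(),
        np.linspace(-1, 1, 21),
        np.linspace(-1, 1, 21),
    )
    soft = np.abs(surf.principal_directions[:, 0])
    assert soft[0] == pytest.approx(soft[1], abs=1e-10)  # (1, -1)/sqrt(2)
    assert surf.anisotropy > 1.0
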