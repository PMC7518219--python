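"""Scripted, reproducible versions of the package's standard experiments.

Each ``run_*`` function builds its parameter variants from the standard
set, runs the simulator, and returns an :class:`ExperimentResult`
bundling tidy tables, the trajectories, and a manifest (full parameters,
seeds, package version) sufficient to re-run the experiment
bit-identically. ``ExperimentResult.save`` writes everything as CSV plus
a JSON manifest.

The experiments:

* ``run_dynamics`` — weight dynamics from zero initial weights
  (weight-vs-time and phase-plot tables).
* ``run_error_descent`` — three trajectories from hand-picked initial
  conditions overlaid on the expected-error surface.
* ``run_competition_ablations`` — six ablations of input correlation,
  reward structure, and motivation, probing which ingredient drives the
  apparent competition between the weights.
* ``run_individuality_sweeps`` — weight clouds across a motivation-peak
  sweep and a balance-reward-slope sweep (individuality / social-reward
  effects).
* ``run_value_probes`` — value time courses at probe inputs and the
  final value landscape (peak-shift diagnostics).

``run_fig3`` .. ``run_fig7`` are thin aliases matching the order in
which the experiments are usually presented.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    competition_metrics,
    error_surface,
    expected_error,
    fixed_point,
    value_landscape,
    value_timecourse,
)
from .learner import Trajectory, run_simulation
from .params import (
    Individual,
    LearningConfig,
    MotivationParams,
    individual_to_dict,
    standard_parameters,
)

__all__ = [
    "ExperimentResult",
    "ablation_variants",
    "run_dynamics",
    "run_error_descent",
    "run_competition_ablations",
    "run_individuality_sweeps",
    "run_value_probes",
    "run_samples",
    "run_fig2",
    "run_fig3",
    "run_fig4",
    "run_fig5",
    "run_fig6",
    "run_fig7",
    "DEFAULT_PROBES",
    "CLOUD_RECORDING",
]

#: Thinned recording window used for weight-cloud sampling: record from
#: step 10,000, every 200 steps, to the 30,000-step horizon.
CLOUD_RECORDING = {"record_start": 10_000, "record_stride": 200}

#: Default value probes: the input-density mode plus the four quadrant
#: centers of the unit square.
DEFAULT_PROBES = (
    (0.5, 0.5),
    (0.25, 0.25),
    (0.25, 0.75),
    (0.75, 0.25),
    (0.75, 0.75),
)


@dataclass
class ExperimentResult:
    """Bundled outputs of one experiment."""

    name: str
    tables: dict[str, pd.DataFrame]
    manifest: dict
    trajectories: dict[str, Trajectory] = field(default_factory=dict)

    def save(self, out_dir) -> None:
        """Write all tables as ``<name>__<table>.csv`` plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(out / f"{self.name}__{key}.csv", index=False)
        with open(out / f"{self.name}__manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=float)


def _manifest(name: str, runs: dict[str, tuple[Individual, LearningConfig]]) -> dict:
    entries = {}
    for key, (ind, cfg) in runs.items():
        c = dataclasses.asdict(cfg)
        c["w0"] = list(cfg.w0)
        entries[key] = {"individual": individual_to_dict(ind), "config": c}
    return {"experiment": name, "version": __version__, "runs": entries}


def run_dynamics(seed: int = 0, n_steps: int = 30_000) -> ExperimentResult:
    """Weight dynamics from zero initial weights at standard parameters."""
    individual, config = standard_parameters()
    config = replace(config, seed=seed, n_steps=n_steps)
    traj = run_simulation(individual, config)
    df = traj.to_dataframe()
    weights = df[["step", "w_b", "w_c"]]
    phase = df[["w_b", "w_c", "step"]]
    metrics = competition_metrics(traj)
    result = ExperimentResult(
        name="dynamics",
        tables={
            "weights": weights,
            "phase": phase,
            "metrics": pd.DataFrame([metrics]),
        },
        manifest=_manifest("dynamics", {"standard": (individual, config)}),
        trajectories={"standard": traj},
    )
    return result


#: Initial weight pairs for the error-descent experiment: one start with
#: especially large error, one with especially small error, one typical.
DESCENT_STARTS = ((-1.0, -1.0), (1.0, -0.6), (0.0, 1.0))


def run_error_descent(seed: int = 0, n_steps: int = 30_000) -> ExperimentResult:
    """Three descent trajectories overlaid on the expected-error surface."""
    individual, base = standard_parameters()
    runs: dict[str, tuple[Individual, LearningConfig]] = {}
    trajectories: dict[str, Trajectory] = {}
    rows = []
    for i, w0 in enumerate(DESCENT_STARTS):
        cfg = replace(base, w0=w0, seed=seed + i, n_steps=n_steps)
        runs[f"start_{i}"] = (individual, cfg)
        traj = run_simulation(individual, cfg)
        trajectories[f"start_{i}"] = traj
        rows.append(
            {
                "start": i,
                "w0_b": w0[0],
                "w0_c": w0[1],
                "E_start": expected_error(w0, individual),
                "w_final_b": traj.w[-1, 0],
                "w_final_c": traj.w[-1, 1],
            }
        )
    fp = fixed_point(individual)
    grid = np.linspace(-1.5, 1.5, 61)
    surface = error_surface(individual, grid, grid)
    traj_table = pd.concat(
        [
            trajectories[k].to_dataframe()[["step", "w_b", "w_c"]].assign(start=i)
            for i, k in enumerate(sorted(trajectories))
        ],
        ignore_index=True,
    )
    result = ExperimentResult(
        name="error_descent",
        tables={
            "starts": pd.DataFrame(rows),
            "surface": surface.to_dataframe(),
            "trajectories": traj_table,
            "fixed_point": pd.DataFrame(
                [{"w_star_b": fp.w_star[0], "w_star_c": fp.w_star[1]}]
            ),
        },
        manifest=_manifest("error_descent", runs),
        trajectories=trajectories,
    )
    return result


def ablation_variants() -> dict[str, tuple[Individual, LearningConfig]]:
    """The six competition ablations, keyed A–F.

    A: no input correlation (rho = 0). B: identical reward structures
    (complexity reward made linear with balance's slope and noise).
    C: constant motivation m = 1. D = C+B, E = C+A, F = A+B. Each is
    otherwise standard. Constant motivation is expressed both in the
    learning config (``constant:1``) and in the individual's motivation
    parameters (m_min = m_max = 1) so simulator and analysis oracle agree.
    """
    base, cfg = standard_parameters()

    def no_corr(ind: Individual) -> Individual:
        return replace(ind, sensory=replace(ind.sensory, rho=0.0))

    def linear_rewards(ind: Individual) -> Individual:
        return replace(
            ind,
            reward=replace(
                ind.reward,
                linear_complexity=True,
                sigma_rc=ind.reward.sigma_rb,
            ),
        )

    def const_m(ind: Individual) -> Individual:
        m = ind.motivation
        return replace(
            ind, motivation=MotivationParams(1.0, 1.0, m.mu_m, m.sigma_m)
        )

    cfg_const = replace(cfg, motivation_mode="constant:1")
    return {
        "A": (no_corr(base), cfg),
        "B": (linear_rewards(base), cfg),
        "C": (const_m(base), cfg_const),
        "D": (const_m(linear_rewards(base)), cfg_const),
        "E": (const_m(no_corr(base)), cfg_const),
        "F": (no_corr(linear_rewards(base)), cfg),
    }


def run_competition_ablations(
    seed: int = 0, n_steps: int = 30_000
) -> ExperimentResult:
    """Run the six ablations and report competition metrics per variant."""
    variants = ablation_variants()
    runs: dict[str, tuple[Individual, LearningConfig]] = {}
    trajectories: dict[str, Trajectory] = {}
    rows = []
    for i, (key, (ind, cfg)) in enumerate(variants.items()):
        cfg = replace(cfg, seed=seed + i, n_steps=n_steps)
        runs[key] = (ind, cfg)
        traj = run_simulation(ind, cfg)
        trajectories[key] = traj
        fp = fixed_point(ind)
        rows.append(
            {
                "variant": key,
                **competition_metrics(traj),
                "w_star_b": fp.w_star[0],
                "w_star_c": fp.w_star[1],
            }
        )
    result = ExperimentResult(
        name="competition_ablations",
        tables={"metrics": pd.DataFrame(rows)},
        manifest=_manifest("competition_ablations", runs),
        trajectories=trajectories,
    )
    return result


#: Sweep values for the individuality experiments.
MU_M_SWEEP = (0.4, 0.6, 0.85)
ALPHA_SWEEP = (0.5, 1.25, 1.7)


def run_individuality_sweeps(
    seed: int = 0, n_seeds: int = 10, n_steps: int = 30_000
) -> ExperimentResult:
    """Weight clouds across the motivation-peak and reward-slope sweeps.

    Each condition is run for ``n_seeds`` replicate seeds with the
    thinned cloud-recording window; the tables report every recorded
    cloud point, per-condition cloud centers with across-seed standard
    errors, and the per-condition fixed point.
    """
    base, cfg0 = standard_parameters()
    cfg0 = replace(cfg0, n_steps=n_steps, **CLOUD_RECORDING)
    conditions: dict[str, Individual] = {}
    for mu_m in MU_M_SWEEP:
        conditions[f"mu_m={mu_m}"] = replace(
            base, motivation=replace(base.motivation, mu_m=mu_m)
        )
    for alpha in ALPHA_SWEEP:
        conditions[f"alpha={alpha}"] = replace(
            base, reward=replace(base.reward, alpha=alpha)
        )

    runs: dict[str, tuple[Individual, LearningConfig]] = {}
    cloud_rows = []
    center_rows = []
    for ci, (label, ind) in enumerate(conditions.items()):
        per_seed_means = []
        for r in range(n_seeds):
            cfg = replace(cfg0, seed=seed + 1000 * ci + r)
            if r == 0:
                runs[label] = (ind, cfg)
            traj = run_simulation(ind, cfg)
            for k in range(len(traj)):
                cloud_rows.append(
                    {
                        "condition": label,
                        "replicate": r,
                        "step": int(traj.step[k]),
                        "w_b": traj.w[k, 0],
                        "w_c": traj.w[k, 1],
                    }
                )
            per_seed_means.append(traj.w.mean(axis=0))
        per_seed_means = np.asarray(per_seed_means)
        center = per_seed_means.mean(axis=0)
        se = per_seed_means.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        fp = fixed_point(ind)
        center_rows.append(
            {
                "condition": label,
                "center_w_b": center[0],
                "center_w_c": center[1],
                "se_w_b": se[0],
                "se_w_c": se[1],
                "w_star_b": fp.w_star[0],
                "w_star_c": fp.w_star[1],
                "n_seeds": n_seeds,
            }
        )
    result = ExperimentResult(
        name="individuality_sweeps",
        tables={
            "clouds": pd.DataFrame(cloud_rows),
            "centers": pd.DataFrame(center_rows),
        },
        manifest=_manifest("individuality_sweeps", runs),
    )
    return result


def run_value_probes(
    seed: int = 0, n_steps: int = 30_000, probes=DEFAULT_PROBES
) -> ExperimentResult:
    """Value time courses at probe inputs plus the final value landscape."""
    individual, config = standard_parameters()
    config = replace(config, seed=seed, n_steps=n_steps)
    traj = run_simulation(individual, config)
    timecourse = value_timecourse(traj, probes, individual.motivation)
    w_final = traj.w[-1]
    landscape = value_landscape(w_final, individual.motivation)
    summary = pd.DataFrame(
        [
            {
                "w_final_b": w_final[0],
                "w_final_c": w_final[1],
                "mode_u_b": landscape.density_mode[0],
                "mode_u_c": landscape.density_mode[1],
                "argmax_u_b": landscape.argmax[0],
                "argmax_u_c": landscape.argmax[1],
                "v_at_mode": landscape.v_at_mode,
                "v_max": landscape.v_max,
            }
        ]
    )
    probe_table = pd.DataFrame(
        [{"probe": i, "u_b": p[0], "u_c": p[1]} for i, p in enumerate(probes)]
    )
    manifest = _manifest("value_probes", {"standard": (individual, config)})
    manifest["probes"] = [list(p) for p in probes]
    result = ExperimentResult(
        name="value_probes",
        tables={
            "timecourse": timecourse,
            "landscape": landscape.to_dataframe(),
            "summary": summary,
            "probes": probe_table,
        },
        manifest=manifest,
        trajectories={"standard": traj},
    )
    return result


def run_samples(seed: int = 0, n_samples: int = 30_000) -> ExperimentResult:
    """Illustrate the model's generative pieces: a sensory-sample cloud,
    the two reward structures, and the motivation function."""
    from .environment import (
        mean_balance_reward,
        mean_complexity_reward,
        mean_motivation,
        sample_balance_reward,
        sample_complexity_reward,
        sample_sensory,
    )

    individual, config = standard_parameters()
    rng = np.random.default_rng(seed)
    u = sample_sensory(individual.sensory, n_samples, rng)
    samples = pd.DataFrame(
        {
            "u_b": u[:, 0],
            "u_c": u[:, 1],
            "m_bar": np.asarray(mean_motivation(u[:, 1], individual.motivation)),
        }
    )
    g = np.linspace(0.0, 1.0, 201)
    curves = pd.DataFrame(
        {
            "u": g,
            "mean_r_b": np.asarray(mean_balance_reward(g, individual.reward.alpha)),
            "mean_r_c": np.asarray(mean_complexity_reward(g, individual.reward)),
            "m_bar": np.asarray(mean_motivation(g, individual.motivation)),
        }
    )
    reward_draws = pd.DataFrame(
        {
            "u": u[:2000, 0],
            "r_b": np.asarray(sample_balance_reward(u[:2000, 0], individual.reward, rng)),
            "u_c": u[:2000, 1],
            "r_c": np.asarray(sample_complexity_reward(u[:2000, 1], individual.reward, rng)),
        }
    )
    manifest = _manifest("samples", {"standard": (individual, config)})
    manifest["n_samples"] = n_samples
    manifest["seed"] = seed
    return ExperimentResult(
        name="samples",
        tables={"samples": samples, "curves": curves, "reward_draws": reward_draws},
        manifest=manifest,
    )


# Aliases in the order the experiments are usually presented.
run_fig2 = run_samples
run_fig3 = run_dynamics
run_fig4 = run_error_descent
run_fig5 = run_competition_ablations
run_fig6 = run_individuality_sweeps
run_fig7 = run_value_probes
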