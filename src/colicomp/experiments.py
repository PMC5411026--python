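"""Simulation campaigns: phase diagrams, producer-fraction sweeps, scenario and
competitor variants, density sweeps, and growth-rate calibration.

Every campaign is exactly reproducible from its master seed: cell- and
replicate-level seeds derive deterministically via seed sequences, and a
completed run appends one CSV row when an output directory is given, so
interrupted sweeps resume where they stopped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import LatticeState
from .metrics import Outcome, classify_outcome, compute_run_metrics, expansion_rate
from .params import ModelParams, ScenarioSpec, Site
from .simulator import Trajectory, run_competition
from .stats import fc_variance_over_time, outcome_distribution
from .synthetic import InoculumSpec, default_s_c_grid, derive_seed, generate_inoculum, \
    single_strain_inoculum

__all__ = [
    "SweepSpec",
    "run_single",
    "sweep_phase_diagram",
    "producer_fraction_sweep",
    "competitor_variants",
    "density_sweep",
    "calibrate_growth_rate",
]


@dataclass
class SweepSpec:
    """Axes and bookkeeping for a parameter sweep.

    ``axes`` maps ModelParams field names to value lists; every grid cell is
    repeated ``reps`` times with deterministically derived seeds.
    """

    axes: dict[str, list[float]]
    reps: int = 48
    base: ModelParams = field(default_factory=ModelParams)
    scenario: ScenarioSpec | None = None
    inoculum: InoculumSpec = field(default_factory=InoculumSpec)
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for name in self.axes:
            if not hasattr(self.base, name):
                raise ValueError(f"unknown parameter axis {name!r}")


def run_single(params: ModelParams, inoculum: InoculumSpec,
               scenario: ScenarioSpec | None = None,
               record_interval: float = 0.5,
               snapshots: bool = True) -> tuple[Trajectory, dict]:
    """One competition run from a fresh inoculum; returns (trajectory, metrics row)."""
    init = generate_inoculum(inoculum, base_pixel_um=params.base_pixel_um)
    traj = run_competition(init, params, scenario=scenario,
                           record_interval=record_interval, store_snapshots=snapshots)
    row = compute_run_metrics(traj, init=init)
    row["inoculum_seed"] = inoculum.seed
    return traj, row


def _append_row(path: Path, row: dict) -> None:
    df = pd.DataFrame([row])
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


def _existing_run_ids(path: Path) -> set:
    if path.exists():
        return set(pd.read_csv(path, usecols=["run_id"])["run_id"])
    return set()


def _write_metadata(out_dir: Path, name: str, payload: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    payload = {"version": __version__, **payload}
    (out_dir / f"{name}.json").write_text(json.dumps(payload, indent=2, default=str))


def sweep_phase_diagram(spec: SweepSpec, record_interval: float = 1.0,
                        snapshots: bool = False) -> pd.DataFrame:
    """Outcome frequencies over a parameter grid (e.g. sigma_x x s_C).

    Returns one row per grid cell with the frequency of each of the four
    outcome classes over ``spec.reps`` runs; frequencies sum to one.  With
    an out_dir, per-run rows are checkpointed to ``runs.csv`` and finished
    runs are skipped on resume.
    """
    names = list(spec.axes)
    grids = [spec.axes[n] for n in names]
    out_path = Path(spec.out_dir) / "runs.csv" if spec.out_dir else None
    done = _existing_run_ids(out_path) if out_path else set()
    if spec.out_dir:
        _write_metadata(Path(spec.out_dir), "sweep_meta", {
            "axes": spec.axes, "reps": spec.reps, "master_seed": spec.master_seed,
            "base": spec.base.__dict__,
            "scenario": spec.scenario.mode.value if spec.scenario else "stochastic",
        })
    rows = []
    mesh = np.meshgrid(*[np.arange(len(g)) for g in grids], indexing="ij")
    cells = np.stack([m.ravel() for m in mesh], axis=1)
    for cell_idx, cell in enumerate(cells):
        values = {n: float(grids[k][cell[k]]) for k, n in enumerate(names)}
        for rep in range(spec.reps):
            run_id = cell_idx * spec.reps + rep
            if run_id in done:
                continue
            sim_seed = derive_seed(spec.master_seed, 2, cell_idx, rep)
            inoc = InoculumSpec(**{**spec.inoculum.__dict__,
                                   "seed": derive_seed(spec.master_seed, 1, cell_idx, rep)})
            params = spec.base.replace(seed=sim_seed, dt=None, **values)
            _, row = run_single(params, inoc, scenario=spec.scenario,
                                record_interval=record_interval, snapshots=snapshots)
            row.update({"run_id": run_id, "cell": cell_idx, **values, "rep": rep})
            rows.append(row)
            if out_path:
                _append_row(out_path, row)
    runs = pd.read_csv(out_path) if out_path else pd.DataFrame(rows)
    classes = [o.value for o in Outcome]
    freq = (runs.groupby([c for c in names])["outcome"]
            .value_counts(normalize=True).unstack(fill_value=0.0)
            .reindex(columns=classes, fill_value=0.0).reset_index())
    return freq


def producer_fraction_sweep(manifest: pd.DataFrame, base: ModelParams | None = None,
                            record_interval: float = 0.5,
                            out_dir: str | None = None) -> pd.DataFrame:
    """Run a fixed-IC manifest (from make_fixed_IC_design): one metrics row per run.

    The returned table carries F_C, outcome, N_C,Edge and the realized mean
    producer fraction per run, suitable for the simulation F_C linear model
    and for producer-fraction response curves.
    """
    base = base or ModelParams()
    out_path = Path(out_dir) / "runs.csv" if out_dir else None
    done = _existing_run_ids(out_path) if out_path else set()
    rows = []
    for rec in manifest.itertuples(index=False):
        if rec.run_id in done:
            continue
        inoc = InoculumSpec(n_cells_total=int(rec.n_cells_total),
                            density_multiplier=int(rec.density_multiplier),
                            spot_diameter_um=float(rec.spot_diameter_um),
                            seed=int(rec.inoculum_seed))
        params = base.replace(s_C=float(rec.s_C), seed=int(rec.sim_seed), dt=None)
        _, row = run_single(params, inoc, record_interval=record_interval)
        row.update({"run_id": rec.run_id, "IC": rec.IC, "rep": rec.rep})
        rows.append(row)
        if out_path:
            _append_row(out_path, row)
    return pd.read_csv(out_path) if out_path else pd.DataFrame(rows)


# competitor configurations: (growth boost over baseline r_X, sensitive?)
COMPETITOR_VARIANTS = {
    "S_RFP": (1.0, True),
    "S_NFP": (1.2, True),
    "R_RFP": (1.0, False),
    "R_NFP": (1.2, False),
}


def competitor_variants(base: ModelParams | None = None, reps: int = 48,
                        master_seed: int = 0, boost: float = 1.2,
                        inoculum: InoculumSpec | None = None,
                        record_interval: float = 1.0) -> dict[str, pd.DataFrame]:
    """Outcome distributions for the four competitor strains at fixed s_C = 0.015.

    S_RFP: baseline sensitive competitor; S_NFP: faster (no fluorophore
    cost, +20% growth by default); R_RFP / R_NFP: toxin-resistant variants
    (sigma_x = 0).  Seeds are paired across variants so differences are not
    driven by inoculum or trajectory noise.
    """
    base = (base or ModelParams()).replace(s_C=0.015, dt=None)
    inoculum = inoculum or InoculumSpec()
    results: dict[str, pd.DataFrame] = {}
    for name, (rel_growth, sensitive) in COMPETITOR_VARIANTS.items():
        params_v = base.replace(
            r_X=base.r_X * (boost if rel_growth != 1.0 else 1.0),
            sigma_x=base.sigma_x if sensitive else 0.0, dt=None)
        outcomes = []
        rows = []
        for rep in range(reps):
            inoc = InoculumSpec(**{**inoculum.__dict__,
                                   "seed": derive_seed(master_seed, 1, rep)})
            params = params_v.replace(seed=derive_seed(master_seed, 2, rep))
            _, row = run_single(params, inoc, record_interval=record_interval,
                                snapshots=False)
            outcomes.append(row["outcome"])
            rows.append(row)
        dist = outcome_distribution(outcomes)
        dist.attrs["runs"] = pd.DataFrame(rows)
        results[name] = dist
    return results


def density_sweep(multipliers=(1, 2, 4, 8), base: ModelParams | None = None,
                  reps: int = 30, master_seed: int = 0, s_C: float = 0.031853929,
                  record_interval: float = 0.5) -> pd.DataFrame:
    """Initial-density variation: outcome distribution and variance statistic.

    Runs ``reps`` competitions per density multiplier at the S5 switching
    rate and reports per density the four outcome frequencies and the
    across-replicate, time-averaged variance of the C fraction dynamics.
    """
    base = (base or ModelParams()).replace(s_C=s_C, dt=None)
    recs = []
    for mult in multipliers:
        trajs, outcomes = [], []
        for rep in range(reps):
            inoc = InoculumSpec(density_multiplier=int(mult),
                                seed=derive_seed(master_seed, 1, mult, rep))
            params = base.replace(seed=derive_seed(master_seed, 2, mult, rep))
            traj, row = run_single(params, inoc, record_interval=record_interval,
                                   snapshots=False)
            trajs.append(traj)
            outcomes.append(row["outcome"])
        dist = outcome_distribution(outcomes)
        rec = {"density_multiplier": mult, "s_C": s_C,
               "fc_variance_over_time": fc_variance_over_time(trajs),
               "n_initial_cells": InoculumSpec(density_multiplier=int(mult)).n_cells}
        for cls in (o.value for o in Outcome):
            rec[cls] = float(dist.loc[cls, "proportion"])
        recs.append(rec)
    return pd.DataFrame(recs)


def calibrate_growth_rate(target_times: np.ndarray, target_areas_um2: np.ndarray,
                          r_values=(2.0, 4.0, 6.0, 8.0), reps: int = 5,
                          base: ModelParams | None = None, master_seed: int = 0,
                          strain: Site = Site.X, record_interval: float = 1.0) -> float:
    """Fit the lattice replication rate to a single-strain area curve.

    Simulates monoclonal colonies over a bracket of replication rates,
    extracts each mean linear-regime expansion slope, and linearly
    interpolates the rate whose slope matches the target's (assuming the
    linear slope-rate relationship).  Raises if the target slope lies
    outside the simulated bracket.
    """
    base = base or ModelParams()
    target_slope = expansion_rate(np.asarray(target_times, float),
                                  np.asarray(target_areas_um2, float))
    r_values = np.sort(np.asarray(r_values, dtype=float))
    slopes = []
    for k, r in enumerate(r_values):
        vals = []
        for rep in range(reps):
            init = single_strain_inoculum(strain=strain,
                                          seed=derive_seed(master_seed, 1, k, rep),
                                          base_pixel_um=base.base_pixel_um)
            params = base.replace(r_C=float(r), r_X=float(r), s_C=0.0, sigma_x=0.0,
                                  seed=derive_seed(master_seed, 2, k, rep), dt=None)
            traj = run_competition(init, params, record_interval=record_interval,
                                   store_snapshots=False)
            vals.append(expansion_rate(traj))
        slopes.append(np.mean(vals))
    slopes = np.asarray(slopes)
    if not (slopes.min() <= target_slope <= slopes.max()):
        raise ValueError(
            f"target slope {target_slope:.3g} um^2/h outside simulated bracket "
            f"[{slopes.min():.3g}, {slopes.max():.3g}]")
    return float(np.interp(target_slope, slopes, r_values))
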