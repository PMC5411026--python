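"""Stochastic lattice kernel: update step, toxin deposition, coarse-graining, runs.

The model follows competition between a heterogeneously toxin-producing
strain C and a competitor X on a 250 x 250 lattice.  Reactions (Moore
neighborhood, diagonal rates scaled by 1/2): replication of viable C and X
into empty agar, stochastic switching C -> C_on, lysis of C_on with
deposition of an exponential colicin profile, and toxin-driven transition
X -> X_stop with hazard sigma_x * (local cumulative toxin).  When the
colony reaches the lattice boundary it is coarse-grained by a factor of
five and re-centred, with replication rates rescaled so the physical front
speed (um/h) is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import C_GROW_ONLY, C_INERT, C_STOCHASTIC
from .lattice import LatticeState
from .params import ModelParams, ScenarioMode, ScenarioSpec, Site, apply_scenario, auto_dt

__all__ = [
    "Trajectory",
    "step",
    "deposit_toxin",
    "coarse_grain",
    "run_competition",
    "steady_state_producer_ratio",
    "steady_state_producer_fraction",
    "well_mixed_producer_ratio",
]

_MAX_ZOOM_EVENTS = 6
_COARSE_FACTOR = 5
_OCCUPANCY_THRESHOLD = 13  # of 25 block sites
_TIME_EPS = 1e-9


def toxin_kernel_table(size: int, n_tox: float, lambda_tox: float, pixel_um: float) -> np.ndarray:
    """(2*size-1)^2 table of n_tox * exp(-d * pixel / lambda), centre (size-1, size-1)."""
    ax = np.arange(-(size - 1), size, dtype=np.float64)
    d = np.hypot(ax[:, None], ax[None, :])
    return n_tox * np.exp(-d * pixel_um / lambda_tox)


def deposit_toxin(toxin: np.ndarray, origin: tuple[int, int], n_tox: float,
                  lambda_tox: float, pixel_size_um: float) -> np.ndarray:
    """Return toxin + n_tox * exp(-d(x, origin) * pixel / lambda) over all sites.

    d is the Euclidean distance in pixels.  Deposition is additive across
    lysis events.
    """
    if lambda_tox <= 0:
        raise ValueError("lambda_tox must be > 0")
    n, m = toxin.shape
    oi, oj = origin
    if not (0 <= oi < n and 0 <= oj < m):
        raise ValueError(f"origin {origin} outside the lattice")
    ii = np.arange(n, dtype=np.float64)[:, None] - oi
    jj = np.arange(m, dtype=np.float64)[None, :] - oj
    d = np.hypot(ii, jj)
    return toxin + n_tox * np.exp(-d * pixel_size_um / lambda_tox)


def _c_mode_for(scenario: ScenarioSpec | None, time: float) -> int:
    if scenario is None:
        return C_STOCHASTIC
    mode = scenario.mode
    if mode in (ScenarioMode.STOCHASTIC, ScenarioMode.ALL_OFF):
        return C_STOCHASTIC
    if mode is ScenarioMode.NON_LYSING_ALL_ON:
        return C_GROW_ONLY
    if mode in (ScenarioMode.SYNC_I, ScenarioMode.SYNC_II):
        grow_h = scenario.sync_grow_minutes / 60.0
        if time < grow_h - _TIME_EPS:
            return C_GROW_ONLY
        return C_INERT
    raise ValueError(f"unknown scenario mode: {mode!r}")


def _step_inplace(state: LatticeState, params: ModelParams, scenario: ScenarioSpec | None,
                  kern: np.ndarray, born: np.ndarray, order: np.ndarray,
                  dt: float | None = None) -> None:
    """Advance state by one sweep of dt hours (mutating)."""
    dt = params.dt if dt is None else dt
    if dt * max(params.r_C, params.r_X) * (4 + 4 * params.diag_factor) > 1.0:
        raise ValueError("probability overflow: dt * (max total per-site rate) > 1")
    is_sync = scenario is not None and scenario.mode in (ScenarioMode.SYNC_I, ScenarioMode.SYNC_II)
    if is_sync and state.time >= scenario.release_time_h - _TIME_EPS:
        # collective release fires once; afterwards no C remain
        _kernels.release_all_c(state.grid, state.toxin, kern)
    c_mode = _c_mode_for(scenario, state.time)
    deposit_on_rep = scenario is not None and scenario.mode is ScenarioMode.NON_LYSING_ALL_ON
    lysis_enabled = not deposit_on_rep
    _kernels.step_kernel(
        state.grid, state.toxin, born, order, _kernels._OFFS, kern,
        params.r_C * dt, params.r_X * dt, params.diag_factor,
        params.s_C * dt, params.d_Con * dt, params.sigma_x * dt,
        c_mode, deposit_on_rep, lysis_enabled, state.rng,
    )
    state.time += dt


def step(state: LatticeState, params: ModelParams,
         scenario: ScenarioSpec | None = None) -> LatticeState:
    """One update step of dt hours; returns a new LatticeState.

    The scenario's parameter adjustments (ALL_OFF, NON_LYSING_ALL_ON) are
    applied here; SYNC schedules are driven by ``state.time``.
    """
    params = apply_scenario(params, scenario)
    new = state.copy()
    kern = toxin_kernel_table(new.size, params.n_tox, params.lambda_tox, new.pixel_size_um)
    born = np.zeros_like(new.grid, dtype=np.uint8)
    order = np.empty(new.grid.size, dtype=np.int64)
    _step_inplace(new, params, scenario, kern, born, order)
    return new


def coarse_grain(state: LatticeState, params: ModelParams) -> tuple[LatticeState, ModelParams]:
    """Coarse-grain by a factor of five and re-centre on a fresh lattice.

    Each 5x5 block maps to AGAR if fewer than 13 of its 25 sites are
    occupied, else to the plurality non-agar state (ties broken by the
    fixed precedence C_on > C > X_stop > X).  Toxin is block-averaged.
    Replication rates are divided by five so the front speed in um/h is
    preserved; per-cell rates (s_C, d_Con, sigma_x) are unchanged.  dt is
    rescaled accordingly (x5, still respecting the probability cap).
    """
    if not state.touches_boundary():
        raise ValueError("coarse_grain called but the colony does not touch the lattice boundary")
    n = state.size
    if n % _COARSE_FACTOR:
        raise ValueError("lattice size must be divisible by 5")
    nb = n // _COARSE_FACTOR
    blocks = state.grid.reshape(nb, _COARSE_FACTOR, nb, _COARSE_FACTOR)
    # counts per state in precedence order C_on > C > X_stop > X
    precedence = (Site.C_ON, Site.C, Site.X_STOP, Site.X)
    counts = np.stack([(blocks == s).sum(axis=(1, 3)) for s in precedence])
    occupied = counts.sum(axis=0)
    winner_idx = counts.argmax(axis=0)  # first (= highest-precedence) maximum
    state_codes = np.array(precedence, dtype=np.int8)
    coarse = np.where(occupied >= _OCCUPANCY_THRESHOLD, state_codes[winner_idx], Site.AGAR.value)

    tox_coarse = state.toxin.reshape(nb, _COARSE_FACTOR, nb, _COARSE_FACTOR).mean(axis=(1, 3))

    off = (n - nb) // 2
    new_grid = np.zeros((n, n), dtype=np.int8)
    new_tox = np.zeros((n, n), dtype=np.float64)
    new_grid[off:off + nb, off:off + nb] = coarse
    new_tox[off:off + nb, off:off + nb] = tox_coarse

    new_state = LatticeState(
        grid=new_grid, toxin=new_tox, zoom_level=state.zoom_level + 1,
        base_pixel_um=state.base_pixel_um, time=state.time, rng=state.rng,
    )
    new_r_C = params.r_C / _COARSE_FACTOR
    new_r_X = params.r_X / _COARSE_FACTOR
    new_dt = min(params.dt * _COARSE_FACTOR,
                 auto_dt(new_r_C, new_r_X, params.s_C, params.d_Con))
    new_params = params.replace(r_C=new_r_C, r_X=new_r_X, dt=new_dt)
    return new_state, new_params


@dataclass
class Trajectory:
    """Recorded time course of one competition run.

    ``snapshots`` holds (time, grid) pairs at each recording point (int8
    copies); ``toxin_snapshots`` holds the matching toxin fields only when
    the run was recorded with ``store_toxin=True`` (the final field is
    always kept in ``final_toxin``).  ``areas_um2`` are physical occupied
    areas per state, continuous across zoom events up to the block-counting
    tolerance of the coarse-graining.
    """

    times: np.ndarray
    counts: np.ndarray          # (n_records, 5) site counts per state
    pixel_um: np.ndarray        # (n_records,)
    zoom_levels: np.ndarray     # (n_records,)
    snapshots: list = field(default_factory=list)
    toxin_snapshots: list | None = None
    final_toxin: np.ndarray | None = None
    zoom_events: list = field(default_factory=list)   # (time, new zoom level)
    params: ModelParams | None = None
    scenario: ScenarioSpec | None = None

    @property
    def areas_um2(self) -> np.ndarray:
        return self.counts * (self.pixel_um ** 2)[:, None]

    def colonized_c_fraction(self) -> np.ndarray:
        """(C + C_on) / colonized area per record; 0 where the colony is empty."""
        occ = self.counts[:, 1:].sum(axis=1).astype(float)
        c = self.counts[:, Site.C] + self.counts[:, Site.C_ON]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(occ > 0, c / occ, 0.0)
        return f

    def snapshot_at(self, time_h: float) -> tuple[float, np.ndarray]:
        """(time, grid) of the recorded snapshot nearest to time_h."""
        if not self.snapshots:
            raise ValueError("trajectory carries no snapshots")
        ts = np.array([t for t, _ in self.snapshots])
        k = int(np.argmin(np.abs(ts - time_h)))
        return self.snapshots[k]

    def state_at(self, time_h: float) -> LatticeState:
        """Reconstruct a LatticeState from the snapshot nearest to time_h."""
        t, grid = self.snapshot_at(time_h)
        k = int(np.argmin(np.abs(self.times - t)))
        if self.toxin_snapshots is not None:
            tox = self.toxin_snapshots[k]
        elif self.final_toxin is not None and k == len(self.times) - 1:
            tox = self.final_toxin
        else:
            tox = np.zeros_like(grid, dtype=np.float64)
        zoom = int(self.zoom_levels[k])
        base = self.pixel_um[k] / 5.0 ** zoom
        return LatticeState(grid=grid.copy(), toxin=np.asarray(tox, dtype=np.float64).copy(),
                            zoom_level=zoom, base_pixel_um=base, time=float(t))

    def to_frame(self):
        """Area time series as a pandas DataFrame (one row per record)."""
        import pandas as pd

        a = self.areas_um2
        return pd.DataFrame({
            "time_h": self.times,
            "zoom_level": self.zoom_levels,
            "pixel_um": self.pixel_um,
            "n_C": self.counts[:, Site.C],
            "n_Con": self.counts[:, Site.C_ON],
            "n_X": self.counts[:, Site.X],
            "n_Xstop": self.counts[:, Site.X_STOP],
            "area_um2_C": a[:, Site.C],
            "area_um2_Con": a[:, Site.C_ON],
            "area_um2_X": a[:, Site.X],
            "area_um2_Xstop": a[:, Site.X_STOP],
        })


def run_competition(init: LatticeState, params: ModelParams,
                    scenario: ScenarioSpec | None = None,
                    record_interval: float = 0.5,
                    store_snapshots: bool = True,
                    store_toxin: bool = False) -> Trajectory:
    """Run a full competition to params.t_end, coarse-graining at the boundary.

    Fully reproducible given ``params.seed``.  Snapshots and per-state
    areas are recorded every ``record_interval`` hours.  Once no viable
    cell remains (C, C_on and X all zero) the lattice is frozen and the
    remaining records are filled in without further stepping.
    """
    params = apply_scenario(params, scenario)
    state = init.copy()
    state.rng = np.random.default_rng(params.seed)

    kern = toxin_kernel_table(state.size, params.n_tox, params.lambda_tox, state.pixel_size_um)
    born = np.zeros_like(state.grid, dtype=np.uint8)
    order = np.empty(state.grid.size, dtype=np.int64)

    n_records = int(round(params.t_end / record_interval)) + 1
    rec_times = np.arange(n_records) * record_interval
    times, counts, pix, zooms, snaps = [], [], [], [], []
    tox_snaps = [] if store_toxin else None
    zoom_events: list[tuple[float, int]] = []

    is_sync = scenario is not None and scenario.mode in (ScenarioMode.SYNC_I, ScenarioMode.SYNC_II)
    release_t = scenario.release_time_h if is_sync else np.inf

    def record() -> np.ndarray:
        c = state.state_counts()
        times.append(state.time)
        counts.append(c)
        pix.append(state.pixel_size_um)
        zooms.append(state.zoom_level)
        if store_snapshots:
            snaps.append((state.time, state.grid.copy()))
            if store_toxin:
                tox_snaps.append(state.toxin.copy())
        return c

    record()
    next_rec = 1
    frozen = False
    while next_rec < n_records:
        target = rec_times[next_rec]
        while state.time < target - _TIME_EPS:
            if state.touches_boundary():
                state, params = coarse_grain(state, params)
                zoom_events.append((state.time, state.zoom_level))
                if len(zoom_events) > _MAX_ZOOM_EVENTS:
                    raise RuntimeError("runaway colony: more than 6 zoom events")
                kern = toxin_kernel_table(state.size, params.n_tox, params.lambda_tox,
                                          state.pixel_size_um)
            dt = min(params.dt, target - state.time)
            if state.time < release_t - _TIME_EPS:
                dt = min(dt, release_t - state.time)
            _step_inplace(state, params, scenario, kern, born, order, dt=dt)
        state.time = target
        c = record()
        next_rec += 1
        if c[Site.C] + c[Site.C_ON] + c[Site.X] == 0:
            frozen = True
            break

    if frozen:
        # nothing can change any more: replicate the last record forward
        last = counts[-1]
        while next_rec < n_records:
            state.time = rec_times[next_rec]
            times.append(state.time)
            counts.append(last.copy())
            pix.append(state.pixel_size_um)
            zooms.append(state.zoom_level)
            if store_snapshots:
                snaps.append((state.time, state.grid.copy()))
                if store_toxin:
                    tox_snaps.append(state.toxin.copy())
            next_rec += 1

    return Trajectory(
        times=np.array(times),
        counts=np.array(counts),
        pixel_um=np.array(pix),
        zoom_levels=np.array(zooms, dtype=int),
        snapshots=snaps,
        toxin_snapshots=tox_snaps,
        final_toxin=state.toxin.copy(),
        zoom_events=zoom_events,
        params=params,
        scenario=scenario,
    )


def steady_state_producer_ratio(params: ModelParams) -> float:
    """Analytic steady-state ratio C_on/C = s_C/d_Con."""
    if params.d_Con == 0:
        raise ZeroDivisionError("d_Con must be > 0")
    return params.s_C / params.d_Con


def steady_state_producer_fraction(params: ModelParams) -> float:
    """Steady-state producer fraction C_on/(C + C_on) = s_C/(s_C + d_Con)."""
    denom = params.s_C + params.d_Con
    if denom == 0:
        raise ZeroDivisionError("s_C + d_Con must be > 0")
    return params.s_C / denom


def well_mixed_producer_ratio(s_C: float, d_Con: float, n_C: int = 2000,
                              t_end: float | None = None, dt: float | None = None,
                              seed: int | None = None,
                              n_batches: int = 20) -> tuple[float, float]:
    """Well-mixed surrogate estimate of the producer ratio C_on/C with its SE.

    Replication is disabled and the viable-C pool is clamped at ``n_C``
    (every switched cell is replaced), the discrete analogue of the
    quasi-steady assumption dCon/dt = s_C*C - d_Con*Con with constant C.
    The time-averaged ratio converges to s_C/d_Con.  The standard error is
    estimated by batch means over ``n_batches`` contiguous blocks after a
    burn-in of 7 producer lifetimes.

    Returns (mean ratio, standard error).
    """
    if d_Con <= 0 or s_C < 0:
        raise ValueError("need d_Con > 0 and s_C >= 0")
    if dt is None:
        dt = min(0.05 / max(s_C, d_Con), 2.0)
    if t_end is None:
        t_end = 300.0 / d_Con  # ~300 producer lifetimes
    rng = np.random.default_rng(seed)
    burn = 7.0 / d_Con
    n_steps = int(np.ceil(t_end / dt))
    con = 0
    samples = []
    # linear per-step probabilities, matching the lattice kernel's update
    # rule; their stationary ratio (s_C dt)/(d_Con dt) is exactly s_C/d_Con
    p_switch = s_C * dt
    p_lyse = d_Con * dt
    for k in range(n_steps):
        switched = rng.binomial(n_C, p_switch)
        lysed = rng.binomial(con, p_lyse) if con else 0
        con += switched - lysed
        if (k + 1) * dt > burn:
            samples.append(con / n_C)
    samples = np.asarray(samples)
    batches = np.array_split(samples, n_batches)
    means = np.array([b.mean() for b in batches])
    se = means.std(ddof=1) / np.sqrt(len(means))
    return float(samples.mean()), float(se)
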