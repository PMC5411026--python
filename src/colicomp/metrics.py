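"""Per-run colony statistics: outcome class, final fraction, edge clusters,
spatial initial-condition metrics, transition time, expansion rates, and the
liquid-culture growth-rate fit.

Thresholds follow the outcome classification used throughout: a strain
dominates above 90% of the colonized area, coexistence spans 10-90%, and a
total colony area below 10^6 um^2 counts as extinction of the community.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage, stats

from .lattice import LatticeState
from .params import Site
from .simulator import Trajectory
from .synthetic import FixtureCurve

__all__ = [
    "Outcome",
    "SpatialInitMetrics",
    "initial_spatial_metrics",
    "count_edge_clusters",
    "final_fraction",
    "classify_outcome",
    "transition_time",
    "expansion_rate",
    "producer_fraction",
    "growth_rate_from_od",
    "compute_run_metrics",
    "EXTINCTION_AREA_UM2",
    "DOMINATION_FRACTION",
]

EXTINCTION_AREA_UM2 = 1e6
DOMINATION_FRACTION = 0.9
PHASE_ONE_END_H = 12.0

_MOORE = np.ones((3, 3), dtype=bool)


class Outcome(str, Enum):
    C_DOMINATION = "C_domination"
    S_DOMINATION = "S_domination"
    COEXISTENCE = "coexistence"
    EXTINCTION = "extinction"


@dataclass(frozen=True)
class SpatialInitMetrics:
    """Initial spatial statistics of the C cells.

    N_C0 is the number of initial C cells.  R_C0 is the norm of the mean
    C-position vector relative to the colony centre (the centre-of-mass
    formula).  D_C0 is the mean Euclidean distance of C cells from their own
    centre of mass, a measure of C spread.  positions_um are C coordinates
    relative to the colony centre.  All lengths in micrometres.
    """

    N_C0: int
    R_C0_um: float
    D_C0_um: float
    positions_um: np.ndarray


def initial_spatial_metrics(state: LatticeState, literal_spread: bool = False) -> SpatialInitMetrics:
    """Spatial metrics of the inoculum (state at time zero).

    The colony centre is the centroid of all occupied sites.  With
    ``literal_spread`` the printed-form spread |mean(x_i - x_bar)| is
    returned for D_C0; it is identically zero and kept only for audit —
    the default is the mean distance mean(|x_i - x_bar|).
    """
    occ = np.argwhere(state.occupied_mask())
    if occ.size == 0:
        raise ValueError("empty lattice")
    c_pos = np.argwhere(state.grid == Site.C)
    if c_pos.size == 0:
        raise ValueError("no C cells in the initial state")
    centre = occ.mean(axis=0)
    rel = (c_pos - centre) * state.pixel_size_um
    mean_vec = rel.mean(axis=0)
    r_c0 = float(np.linalg.norm(mean_vec))
    dev = rel - mean_vec
    if literal_spread:
        d_c0 = float(np.linalg.norm(dev.mean(axis=0)))
    else:
        d_c0 = float(np.linalg.norm(dev, axis=1).mean())
    return SpatialInitMetrics(N_C0=len(c_pos), R_C0_um=r_c0, D_C0_um=d_c0, positions_um=rel)


def _external_background(grid: np.ndarray) -> np.ndarray:
    """Agar connected (8-connectivity) to the lattice border."""
    agar = grid == Site.AGAR
    lbl, n = ndimage.label(agar, structure=_MOORE)
    border = np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    ext_labels = np.unique(border[border > 0])
    return np.isin(lbl, ext_labels)


def colony_edge_mask(grid: np.ndarray) -> np.ndarray:
    """Occupied sites bordering the colony's external background.

    A site is on the colony edge if it is occupied and has at least one
    Moore neighbor in the external background (agar connected to the
    lattice border), or sits on the lattice border itself.
    """
    occ = grid != Site.AGAR
    ext = _external_background(grid)
    near_ext = ndimage.binary_dilation(ext, structure=_MOORE)
    on_border = np.zeros_like(occ)
    on_border[0, :] = on_border[-1, :] = True
    on_border[:, 0] = on_border[:, -1] = True
    return occ & (near_ext | on_border)


def count_edge_clusters(state: LatticeState | np.ndarray) -> int:
    """Number of viable C clusters touching the colony edge (N_C,Edge).

    Clusters are 8-connected components of {C, C_on} sites.  A cluster is
    counted if it is viable (contains at least one reproducing C site) and
    reaches the colony edge.  Evaluated on the 12-h snapshot in the phase-1
    analysis.
    """
    grid = state.grid if isinstance(state, LatticeState) else np.asarray(state)
    if not (grid != Site.AGAR).any():
        raise ValueError("empty colony")
    cmask = (grid == Site.C) | (grid == Site.C_ON)
    if not cmask.any():
        return 0
    edge = colony_edge_mask(grid)
    lbl, n = ndimage.label(cmask, structure=_MOORE)
    if n == 0:
        return 0
    has_c = np.bincount(lbl[grid == Site.C], minlength=n + 1)[1:] > 0
    at_edge = np.bincount(lbl[edge & cmask], minlength=n + 1)[1:] > 0
    return int(np.sum(has_c & at_edge))


def final_fraction(traj: Trajectory) -> float:
    """F_C: C-lineage share of the colonized area at the end of the run."""
    c = traj.counts[-1]
    occ = c[1:].sum()
    if occ == 0:
        return 0.0
    return float((c[Site.C] + c[Site.C_ON]) / occ)


def classify_outcome(f_c: float, total_area_um2: float) -> Outcome:
    """Classify one run: extinction below 10^6 um^2 (checked first), then
    domination above 90% / below 10% of colony area, else coexistence."""
    if not (np.isfinite(f_c) and np.isfinite(total_area_um2)):
        raise ValueError("inputs must be finite")
    if total_area_um2 < EXTINCTION_AREA_UM2:
        return Outcome.EXTINCTION
    if f_c > DOMINATION_FRACTION:
        return Outcome.C_DOMINATION
    if f_c < 1.0 - DOMINATION_FRACTION:
        return Outcome.S_DOMINATION
    return Outcome.COEXISTENCE


def transition_time(traj: Trajectory, sustain: int = 2) -> float:
    """First time C holds more than half the colonized area, sustained.

    The crossing must hold for the next ``sustain`` recorded points
    (debouncing single-snapshot noise).  Returns NaN if C never captures
    half the colony.
    """
    f = traj.colonized_c_fraction()
    above = f > 0.5
    n = len(above)
    for k in range(n):
        if above[k] and above[k:k + sustain + 1].all():
            return float(traj.times[k])
    return float("nan")


def _best_linear_window(x: np.ndarray, y: np.ndarray, min_frac: float = 0.25,
                        min_points: int = 6, r2_min: float = 0.98):
    """Best linear window covering >= 25% of the series.

    Among windows with R^2 >= r2_min, picks the one maximizing R^2 (binned
    at 1e-3 so that equally clean windows tie) and, within that bin, the
    longest — so a noiseless linear regime is fitted over its full extent
    while windows contaminated by lag or saturation lose.  Returns
    (slope, intercept, r2, start, stop); raises if no admissible window is
    linear enough.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    min_len = max(min_points, int(np.ceil(min_frac * n)))
    if n < min_len:
        raise ValueError(f"need at least {min_len} points, got {n}")
    # windowed sums via prefix sums (demeaned for numerical headroom)
    xc = x - x.mean()
    yc = y - y.mean()
    z = np.zeros(1)
    cx, cy = np.r_[z, np.cumsum(xc)], np.r_[z, np.cumsum(yc)]
    cxx, cyy = np.r_[z, np.cumsum(xc * xc)], np.r_[z, np.cumsum(yc * yc)]
    cxy = np.r_[z, np.cumsum(xc * yc)]
    best = None  # (r2 bin, length, r2, start, stop)
    for length in range(min_len, n + 1):
        starts = np.arange(0, n - length + 1)
        stops = starts + length
        sx = cx[stops] - cx[starts]
        sy = cy[stops] - cy[starts]
        sxx = cxx[stops] - cxx[starts]
        syy = cyy[stops] - cyy[starts]
        sxy = cxy[stops] - cxy[starts]
        vxx = sxx - sx * sx / length
        vyy = syy - sy * sy / length
        vxy = sxy - sx * sy / length
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where((vxx > 0) & (vyy > 0), vxy ** 2 / (vxx * vyy), 0.0)
        ok = r2 >= r2_min
        if not ok.any():
            continue
        k = int(np.argmax(np.where(ok, r2, -np.inf)))
        key = (np.floor(r2[k] * 1000) / 1000, length)
        if best is None or key >= best[0]:
            best = (key, r2[k], int(starts[k]), int(stops[k]))
    if best is None:
        raise ValueError(f"no window of >= {min_len} points reaches R^2 >= {r2_min}")
    _, r2_best, start, stop = best
    res = stats.linregress(x[start:stop], y[start:stop])
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), start, stop


def expansion_rate(times: "np.ndarray | Trajectory", areas_um2: np.ndarray | None = None,
                   r2_min: float = 0.98) -> float:
    """Colony expansion rate (um^2/h) from the linear area-growth regime.

    The linear regime is the longest window covering at least a quarter of
    the series that reaches R^2 >= 0.98; the fitted slope is returned.
    Accepts a Trajectory (total colonized area) or explicit (times, areas).
    """
    if isinstance(times, Trajectory):
        traj = times
        areas_um2 = traj.areas_um2[:, 1:].sum(axis=1)
        times = traj.times
    times = np.asarray(times, dtype=float)
    areas_um2 = np.asarray(areas_um2, dtype=float)
    slope, _, _, _, _ = _best_linear_window(times, areas_um2, r2_min=r2_min)
    return float(slope)


def producer_fraction(obj) -> "float | np.ndarray":
    """C_on / (C + C_on): scalar for a LatticeState, series for a Trajectory.

    Records with no C-lineage sites are flagged NaN.
    """
    if isinstance(obj, LatticeState):
        c = obj.state_counts()
        tot = c[Site.C] + c[Site.C_ON]
        return float(c[Site.C_ON] / tot) if tot > 0 else float("nan")
    if isinstance(obj, Trajectory):
        c = obj.counts[:, Site.C].astype(float)
        con = obj.counts[:, Site.C_ON].astype(float)
        tot = c + con
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, con / tot, np.nan)
    c, con = obj
    c = np.asarray(c, dtype=float)
    con = np.asarray(con, dtype=float)
    tot = c + con
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, con / tot, np.nan)


def growth_rate_from_od(curve: FixtureCurve, r2_min: float = 0.98) -> float:
    """Population growth rate GR = b / ln 2 (doublings per hour).

    b is the slope of ln(OD) against time fitted in the exponential phase,
    detected with the same longest-high-R^2 window rule as the colony
    expansion-rate fit.
    """
    if np.any(curve.values <= 0):
        raise ValueError("OD values must be positive")
    slope, _, _, _, _ = _best_linear_window(curve.times, np.log(curve.values), r2_min=r2_min)
    return float(slope / np.log(2.0))


def compute_run_metrics(traj: Trajectory, init: LatticeState | None = None,
                        phase1_h: float = PHASE_ONE_END_H) -> dict:
    """One row of per-run statistics (keys match the metrics CSV columns).

    N_C_Edge needs the recorded snapshot nearest ``phase1_h``; spatial
    initial metrics need the inoculum (``init`` or the t=0 snapshot).
    """
    f_c = final_fraction(traj)
    total = float(traj.areas_um2[-1, 1:].sum())
    out = classify_outcome(f_c, total)
    row = {
        "F_C": f_c,
        "total_area_um2": total,
        "outcome": out.value,
        "transition_time_h": transition_time(traj),
        "mean_producer_fraction": float(np.nanmean(producer_fraction(traj))),
    }
    try:
        row["expansion_rate_um2_per_h"] = expansion_rate(traj)
    except ValueError:
        row["expansion_rate_um2_per_h"] = float("nan")
    if traj.snapshots:
        _, grid12 = traj.snapshot_at(phase1_h)
        row["N_C_Edge"] = count_edge_clusters(grid12) if (grid12 != Site.AGAR).any() else 0
    if init is None and traj.snapshots and traj.snapshots[0][0] == 0.0:
        init = traj.state_at(0.0)
    if init is not None and (init.grid == Site.C).any():
        sp = initial_spatial_metrics(init)
        row.update({"N_C0": sp.N_C0, "R_C0_um": sp.R_C0_um, "D_C0_um": sp.D_C0_um})
    if traj.params is not None:
        row.update({"s_C": traj.params.s_C, "sigma_x": traj.params.sigma_x,
                    "seed": traj.params.seed})
    if traj.scenario is not None:
        row["scenario"] = traj.scenario.mode.value
    return row
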