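"""Synthetic inputs: inoculum lattices, fixed-IC replication designs, fixture data.

Inocula emulate the experimental acoustic spotting: ~150 cells at a C:X
ratio of about 1:100 scattered uniformly in a ~450 um disc, conditioned on
at least one C cell.  Fixture curves and regression tables carry their
generating truth so the fitting and statistics stages can be tested for
recovery without experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import DEFAULT_LATTICE_SIZE, LatticeState
from .params import Site

__all__ = [
    "InoculumSpec",
    "FixtureCurve",
    "generate_inoculum",
    "single_strain_inoculum",
    "make_fixed_IC_design",
    "synthetic_od_curve",
    "synthetic_regression_table",
    "derive_seed",
]


def derive_seed(*keys: int) -> int:
    """Deterministic child seed (< 2**31) from a tuple of integer keys."""
    state = np.random.SeedSequence(list(keys)).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


@dataclass(frozen=True)
class InoculumSpec:
    """Spotting specification for the initial community."""

    n_cells_total: int = 150
    ratio_C_to_X: tuple[int, int] = (1, 100)
    spot_diameter_um: float = 450.0
    density_multiplier: int = 1
    require_min_one_C: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_total < 1:
            raise ValueError("n_cells_total must be >= 1")
        if self.density_multiplier not in (1, 2, 4, 8):
            raise ValueError("density_multiplier must be one of 1, 2, 4, 8")
        if min(self.ratio_C_to_X) < 0 or self.ratio_C_to_X[0] + self.ratio_C_to_X[1] == 0:
            raise ValueError("invalid C:X ratio")

    @property
    def n_cells(self) -> int:
        return self.n_cells_total * self.density_multiplier

    @property
    def p_C(self) -> float:
        c, x = self.ratio_C_to_X
        return c / (c + x)


def _disc_sites(size: int, radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    centre = (size - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    mask = (ii - centre) ** 2 + (jj - centre) ** 2 <= radius_px ** 2
    return ii[mask], jj[mask]


def generate_inoculum(spec: InoculumSpec, base_pixel_um: float = 2.0,
                      size: int = DEFAULT_LATTICE_SIZE) -> LatticeState:
    """Place the inoculum uniformly at random (no collisions) in the centred disc.

    Each cell is C with probability 1/(1+ratio) independently; the label
    assignment is resampled until at least one C cell is present when the
    spec requires it.  Toxin is zero and the clock starts at zero.
    """
    radius_px = spec.spot_diameter_um / 2.0 / base_pixel_um
    if 2 * radius_px > size:
        raise ValueError("spot does not fit in the lattice at this pixel size")
    ii, jj = _disc_sites(size, radius_px)
    n = spec.n_cells
    if n > ii.size:
        raise ValueError(f"disc has {ii.size} sites but {n} cells requested")
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(ii.size, size=n, replace=False)
    is_c = rng.random(n) < spec.p_C
    if spec.require_min_one_C and spec.p_C > 0:
        while not is_c.any():
            is_c = rng.random(n) < spec.p_C
    grid = np.zeros((size, size), dtype=np.int8)
    grid[ii[chosen], jj[chosen]] = np.where(is_c, Site.C.value, Site.X.value)
    return LatticeState(grid=grid, toxin=np.zeros((size, size)), zoom_level=0,
                        base_pixel_um=base_pixel_um, time=0.0,
                        rng=np.random.default_rng(spec.seed))


def single_strain_inoculum(strain: Site = Site.X, n_cells: int = 150,
                           spot_diameter_um: float = 450.0, seed: int = 0,
                           base_pixel_um: float = 2.0,
                           size: int = DEFAULT_LATTICE_SIZE) -> LatticeState:
    """Monoclonal spot for single-strain control runs (growth calibration)."""
    state = generate_inoculum(
        InoculumSpec(n_cells_total=n_cells, ratio_C_to_X=(0, 1), spot_diameter_um=spot_diameter_um,
                     require_min_one_C=False, seed=seed),
        base_pixel_um=base_pixel_um, size=size)
    if strain != Site.X:
        state.grid[state.grid == Site.X.value] = np.int8(strain.value)
    return state


def make_fixed_IC_design(n_IC: int = 16, reps: int = 30,
                         s_C_values: "np.ndarray | list[float] | None" = None,
                         master_seed: int = 0,
                         inoculum_spec: InoculumSpec | None = None) -> pd.DataFrame:
    """Run manifest for the fixed-initial-condition replication design.

    Returns one row per run: n_IC frozen inoculum layouts, each paired with
    ``reps`` distinct simulation seeds for every switching rate (default
    16 x 30 x 17 = 8,160 runs).  Seeds derive deterministically from the
    master seed so the manifest is reproducible.
    """
    if n_IC < 1 or reps < 1:
        raise ValueError("n_IC and reps must be >= 1")
    if s_C_values is None:
        s_C_values = default_s_c_grid()
    s_C_values = np.asarray(s_C_values, dtype=float)
    base = inoculum_spec or InoculumSpec()
    rows = []
    run_id = 0
    for ic in range(n_IC):
        ic_seed = derive_seed(master_seed, 1, ic)
        for k, s_c in enumerate(s_C_values):
            for rep in range(reps):
                rows.append({
                    "run_id": run_id,
                    "IC": ic,
                    "inoculum_seed": ic_seed,
                    "s_C": float(s_c),
                    "rep": rep,
                    "sim_seed": derive_seed(master_seed, 2, ic, k, rep),
                    "n_cells_total": base.n_cells_total,
                    "density_multiplier": base.density_multiplier,
                    "spot_diameter_um": base.spot_diameter_um,
                })
                run_id += 1
    return pd.DataFrame(rows)


def default_s_c_grid(n: int = 17, s_min: float = 0.001, s_max: float = 0.155) -> np.ndarray:
    """The default 17-value switching-rate grid.

    Log-spaced between the low and high exemplar switching rates (0.001 and
    0.155 per hour), covering the scanned producer-fraction range.
    """
    return np.geomspace(s_min, s_max, n)


@dataclass
class FixtureCurve:
    """A synthetic time series with its generating truth attached."""

    times: np.ndarray
    values: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def synthetic_od_curve(gr_per_h: float, od0: float = 0.1, noise_cv: float = 0.0,
                       times: "np.ndarray | None" = None,
                       seed: int | None = None) -> FixtureCurve:
    """Exponential OD curve: od0 * exp(b t) with b = gr * ln 2, lognormal noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    noise.  The generating growth rate (doublings/h) is stored in truth.
    """
    if gr_per_h <= 0:
        raise ValueError("gr_per_h must be > 0")
    if times is None:
        times = np.arange(0, 18.0, 0.25)  # 15-min plate-reader sampling over 18 h
    times = np.asarray(times, dtype=float)
    b = gr_per_h * np.log(2.0)
    values = od0 * np.exp(b * times)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        values = values * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=times.size)
    return FixtureCurve(times=times, values=values,
                        truth={"gr_per_h": gr_per_h, "od0": od0, "noise_cv": noise_cv,
                               "slope_ln": b})


def synthetic_regression_table(betas: dict, design: dict, noise_sd: float,
                               n: int, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic run table from a stated linear model.

    Parameters
    ----------
    betas : dict
        Term -> effect.  For a continuous predictor a scalar slope; for a
        categorical predictor an array of per-level effects (mean-centred
        internally); for an interaction a tuple key ``(a, b)`` with a
        scalar (continuous x continuous) or per-level slope array
        (categorical x continuous).
    design : dict
        Predictor name -> {"kind": "continuous"} or
        {"kind": "categorical", "levels": int}.
    noise_sd : float
        Gaussian noise standard deviation on the response.
    n : int
        Number of rows.

    Continuous predictors are standard normal; categorical levels are
    drawn uniformly, so all predictors are independent and the analytic
    variance decomposition in ``truth`` (stored in ``df.attrs``) applies.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    numeric: dict[str, np.ndarray] = {}
    for name, spec in design.items():
        kind = spec["kind"]
        if kind == "continuous":
            x = rng.standard_normal(n)
            cols[name] = x
            numeric[name] = x
        elif kind == "categorical":
            k = int(spec["levels"])
            lv = rng.integers(0, k, size=n)
            cols[name] = lv
        else:
            raise ValueError(f"unknown predictor kind {kind!r} for {name!r}")

    y = np.zeros(n)
    var_shares: dict = {}
    for term, beta in betas.items():
        if isinstance(term, tuple):
            a, b = term
            if design[a]["kind"] == "categorical" and design[b]["kind"] == "continuous":
                eff = np.asarray(beta, dtype=float)
                if eff.size != design[a]["levels"]:
                    raise ValueError(f"interaction {term}: need one slope per level of {a}")
                eff = eff - eff.mean()
                contrib = eff[cols[a]] * numeric[b]
                var = np.mean(eff ** 2)
            elif design[a]["kind"] == "continuous" and design[b]["kind"] == "continuous":
                contrib = float(beta) * numeric[a] * numeric[b]
                var = float(beta) ** 2
            else:
                raise ValueError(f"unsupported interaction kind for {term}")
        else:
            if design[term]["kind"] == "continuous":
                contrib = float(beta) * numeric[term]
                var = float(beta) ** 2
            else:
                eff = np.asarray(beta, dtype=float)
                if eff.size != design[term]["levels"]:
                    raise ValueError(f"{term}: need one effect per level")
                eff = eff - eff.mean()
                contrib = eff[cols[term]]
                var = np.mean(eff ** 2)
        y = y + contrib
        var_shares[term] = var
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=n)

    total_var = sum(var_shares.values()) + noise_sd ** 2
    eta2 = {t: v / total_var for t, v in var_shares.items()} if total_var > 0 else {}

    df = pd.DataFrame(cols)
    df["response"] = y
    df.attrs["truth"] = {"betas": betas, "noise_sd": noise_sd, "eta2": eta2}
    return df
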