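"""Shared fixtures: small lattices and inocula sized for fast unit tests."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from colicomp import InoculumSpec, LatticeState, ModelParams, Site, generate_inoculum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Fast parameter set for a 50x50 unit-test lattice."""
    return ModelParams(r_C=5.4, r_X=5.4, s_C=0.02, d_Con=1.2, t_end=4.0, seed=7)


@pytest.fixture
def small_inoculum():
    """~30 cells in a 60 um spot on a 50x50 lattice (2 um pixels)."""
    spec = InoculumSpec(n_cells_total=30, spot_diameter_um=60.0, seed=11)
    return generate_inoculum(spec, base_pixel_um=2.0, size=50)


def random_mixed_lattice(rng, size=50, p_occ=0.4):
    """Random lattice over all five states, plus a random toxin field."""
    probs = [1 - p_occ, p_occ * 0.3, p_occ * 0.1, p_occ * 0.45, p_occ * 0.15]
    grid = rng.choice(5, size=(size, size), p=probs).astype(np.int8)
    toxin = rng.exponential(1e-4, size=(size, size))
    return LatticeState(grid=grid, toxin=toxin, base_pixel_um=2.0,
                        rng=np.random.default_rng(rng.integers(2**31)))


@pytest.fixture
def mixed_lattice(rng):
    return random_mixed_lattice(rng)
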