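"""The simulated colony state: agent lattice, cumulative toxin field, zoom bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Site

__all__ = ["LatticeState", "DEFAULT_LATTICE_SIZE"]

DEFAULT_LATTICE_SIZE = 250

_N_STATES = 5


@dataclass
class LatticeState:
    """Per-site agent states plus the cumulative colicin field.

    The lattice is square (default 250 x 250).  ``pixel_size_um`` grows by a
    factor of five at every coarse-graining (zoom) event so the physical
    field of view follows the expanding colony.
    """

    grid: np.ndarray
    toxin: np.ndarray
    zoom_level: int = 0
    base_pixel_um: float = 2.0
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        self.grid = np.ascontiguousarray(self.grid, dtype=np.int8)
        self.toxin = np.ascontiguousarray(self.toxin, dtype=np.float64)
        if self.grid.shape != self.toxin.shape or self.grid.ndim != 2:
            raise ValueError("grid and toxin must be 2-D arrays of identical shape")
        if self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("lattice must be square")
        if np.any(self.toxin < 0):
            raise ValueError("toxin field must be non-negative")
        if self.grid.min() < 0 or self.grid.max() >= _N_STATES:
            raise ValueError("grid contains unknown site states")

    @classmethod
    def empty(cls, size: int = DEFAULT_LATTICE_SIZE, base_pixel_um: float = 2.0,
              seed: int | None = None) -> "LatticeState":
        return cls(
            grid=np.zeros((size, size), dtype=np.int8),
            toxin=np.zeros((size, size), dtype=np.float64),
            base_pixel_um=base_pixel_um,
            rng=np.random.default_rng(seed),
        )

    @property
    def size(self) -> int:
        return self.grid.shape[0]

    @property
    def pixel_size_um(self) -> float:
        return self.base_pixel_um * 5.0 ** self.zoom_level

    def copy(self) -> "LatticeState":
        return LatticeState(
            grid=self.grid.copy(),
            toxin=self.toxin.copy(),
            zoom_level=self.zoom_level,
            base_pixel_um=self.base_pixel_um,
            time=self.time,
            rng=self.rng,
        )

    def state_counts(self) -> np.ndarray:
        """Site counts per state, indexed by :class:`Site` value."""
        return np.bincount(self.grid.ravel(), minlength=_N_STATES)

    def occupied_mask(self) -> np.ndarray:
        return self.grid != Site.AGAR

    def touches_boundary(self) -> bool:
        """True if the occupied region reaches any lattice edge (zoom trigger)."""
        g = self.grid
        return bool(
            (g[0, :] != 0).any() or (g[-1, :] != 0).any()
            or (g[:, 0] != 0).any() or (g[:, -1] != 0).any()
        )

    def area_um2(self) -> np.ndarray:
        """Physical occupied area per state (um^2), indexed by Site value."""
        return self.state_counts() * self.pixel_size_um ** 2
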