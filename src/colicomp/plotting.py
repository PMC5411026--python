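"""Snapshot rendering and phase-diagram heatmaps (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .lattice import LatticeState
from .params import Site

__all__ = ["LATTICE_CMAP", "render_snapshot", "save_snapshot_png", "phase_diagram_heatmap"]

# palette: agar black; reproducing C green; producing C white;
# living S bright magenta; inhibited S dark magenta
_PALETTE = {
    Site.AGAR: "#000000",
    Site.C: "#2ca02c",
    Site.C_ON: "#ffffff",
    Site.X: "#ff00ff",
    Site.X_STOP: "#7a0f6e",
}
LATTICE_CMAP = ListedColormap([_PALETTE[s] for s in Site])


def render_snapshot(state: "LatticeState | np.ndarray", ax=None, title: str | None = None):
    """Draw one lattice snapshot with the strain palette; returns the axes."""
    grid = state.grid if isinstance(state, LatticeState) else np.asarray(state)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(grid, cmap=LATTICE_CMAP, vmin=0, vmax=len(Site) - 1, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    if isinstance(state, LatticeState):
        ax.set_xlabel(f"{state.size * state.pixel_size_um / 1000:.2f} mm, t = {state.time:.1f} h")
    return ax


def save_snapshot_png(state: "LatticeState | np.ndarray", path: str,
                      title: str | None = None) -> None:
    ax = render_snapshot(state, title=title)
    fig = ax.figure
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def phase_diagram_heatmap(freq_table, x_col: str, y_col: str, outcome: str, path: str | None = None):
    """Heatmap of one outcome's frequency over a two-axis sweep table."""
    pivot = freq_table.pivot(index=y_col, columns=x_col, values=outcome)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, vmin=0, vmax=1,
                       shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label=f"frequency of {outcome}")
    ax.set_xlabel(x_col)
    ax.set_ylabel(y_col)
    if path:
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
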