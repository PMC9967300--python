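"""Figure rendering: contact-map heat maps and 2D histograms.

Every figure has a CSV twin written by the pipeline; nothing exists
only as pixels.  Colour scales are logarithmic, matching how sparse
contact probabilities and histogram counts are usually displayed.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LogNorm

from .clustering import Histogram2D
from .contacts import ContactMatrix
from .trajectory import ResidueMap

__all__ = ["plot_contact_map", "plot_histogram2d"]


def plot_contact_map(
    cm: ContactMatrix,
    rmap: ResidueMap | None = None,
    path: str | Path | None = None,
    mask_diagonal: bool = True,
):
    """Heat map of contact probabilities, dye rows/columns highlighted."""
    P = cm.P.copy()
    if mask_diagonal:
        np.fill_diagonal(P, np.nan)
    P = np.where(P > 0, P, np.nan)  # log scale: zero probability -> blank
    fig, ax = plt.subplots(figsize=(6, 5))
    extent = (
        cm.residue_ids[0] - 0.5,
        cm.residue_ids[-1] + 0.5,
        cm.residue_ids[-1] + 0.5,
        cm.residue_ids[0] - 0.5,
    )
    vmin = np.nanmin(P) if np.isfinite(P).any() else 1e-3
    im = ax.imshow(P, norm=LogNorm(vmin=max(vmin, 1e-4), vmax=1.0),
                   cmap="viridis", extent=extent)
    if rmap is not None:
        for rid in rmap.dye_residues():
            for coord in ("axvline", "axhline"):
                getattr(ax, coord)(rid, color="magenta", ls="--", lw=0.8)
    ax.set_xlabel("residue ID")
    ax.set_ylabel("residue ID")
    ax.set_title(f"contact probability (cutoff {cm.cutoff} nm)")
    fig.colorbar(im, ax=ax, label="P(contact)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_histogram2d(h: Histogram2D, path: str | Path | None = None):
    """Joint histogram with log colour scale and marginal-style labels."""
    fig, ax = plt.subplots(figsize=(6, 5))
    counts = np.where(h.counts > 0, h.counts, np.nan)
    im = ax.pcolormesh(h.x_edges, h.y_edges, counts.T,
                       norm=LogNorm(vmin=1, vmax=max(h.counts.max(), 1)),
                       cmap="viridis")
    ax.set_xlabel(h.x_label)
    ax.set_ylabel(h.y_label)
    fig.colorbar(im, ax=ax, label="frames per bin")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
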