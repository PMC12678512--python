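"""Static figure exports for the pipeline's standard analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .landscape import FreeEnergyLandscape
from .solvation import RadialDistribution
from .superpose import FlexibilityProfile

__all__ = ["plot_landscape", "plot_occupancy", "plot_rdf", "plot_rmsf", "plot_series"]


def plot_landscape(
    landscape: FreeEnergyLandscape,
    representatives: list[tuple[float, float]] | None = None,
    path: str | None = None,
    dg_max: float | None = None,
):
    """Free-energy heatmap over (d1, d2) with optional cluster-center markers
    (undefined bins render at the top of the colour scale)."""
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    dG = landscape.dG.copy()
    top = dg_max if dg_max is not None else (np.nanmax(dG) if np.isfinite(np.nanmax(dG)) else 1.0)
    img = np.where(landscape.occupied_mask, dG, top)
    mesh = ax.pcolormesh(
        landscape.d1_edges, landscape.d2_edges, img.T, cmap="jet", vmax=top, shading="flat"
    )
    fig.colorbar(mesh, ax=ax, label=r"relative $\Delta G$ (kcal/mol)")
    if representatives:
        d1s, d2s = zip(*representatives)
        ax.scatter(d1s, d2s, marker="^", c="black", s=45, label="cluster centers")
        ax.legend(loc="upper left", frameon=False)
    ax.set_xlabel(r"TYR7$-$VAL34 separation ($\mathrm{\AA}$)")
    ax.set_ylabel(r"ILE45$-$VAL70 separation ($\mathrm{\AA}$)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_occupancy(occupancy: np.ndarray, path: str | None = None):
    """Helicity occupancy map: white fully helical, black non-helical,
    gray partial."""
    fig, ax = plt.subplots(figsize=(6.4, 3.2))
    ax.imshow(
        occupancy,
        aspect="auto",
        origin="lower",
        cmap="gray",
        vmin=0.0,
        vmax=1.0,
        interpolation="nearest",
    )
    ax.set_xlabel("residue")
    ax.set_ylabel("trajectory-fraction bin")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_rdf(distributions: dict[str, RadialDistribution], path: str | None = None):
    fig, ax = plt.subplots(figsize=(5.6, 3.8))
    for label, dist in distributions.items():
        ax.plot(dist.r_centers, dist.g, label=label)
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel(r"r ($\mathrm{\AA}$)")
    ax.set_ylabel("g(r)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_rmsf(profile: FlexibilityProfile, path: str | None = None):
    fig, ax = plt.subplots(figsize=(5.6, 3.2))
    ax.plot(profile.residue_indices, profile.per_residue_rmsf, lw=1.2)
    ax.axhline(profile.threshold, color="crimson", lw=0.9, ls="--", label="mean + sd")
    for lo, hi in profile.peak_regions:
        ax.axvspan(lo - 0.5, hi + 0.5, color="crimson", alpha=0.15)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"RMSF ($\mathrm{\AA}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_series(series: dict[str, np.ndarray], timestep: float, path: str | None = None, ylabel: str = ""):
    fig, ax = plt.subplots(figsize=(5.6, 3.2))
    for label, y in series.items():
        ax.plot(np.arange(len(y)) * timestep, y, lw=0.9, label=label)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
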