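"""Radial solvent distribution about a protein region's center of mass.

Solvent reference sites (oxygen for water-like residues, carbon for
chloroform-like ones) are binned into spherical shells around the region COM
under the minimum-image convention for an orthorhombic box, and the shell
density is normalized by the bulk density N/V so that g(r) -> 1 far from the
protein. Poisson standard errors on shell counts are propagated so that
condition/region profiles can be compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Trajectory, center_of_mass

__all__ = [
    "SolventSelector",
    "RadialDistribution",
    "radial_solvent_distribution",
    "compare_distributions",
    "WATER_SELECTOR",
    "CHLOROFORM_SELECTOR",
]


@dataclass(frozen=True)
class SolventSelector:
    """Which residues count as solvent and which atom is the reference site."""

    residue_names: frozenset
    site_atom: str

    def site_indices(self, trajectory: Trajectory) -> np.ndarray:
        top = trajectory.topology
        idx = [
            i
            for i, a in enumerate(top.atoms)
            if a.residue_name.upper() in self.residue_names and a.name == self.site_atom
        ]
        return np.array(idx, dtype=int)


WATER_SELECTOR = SolventSelector(frozenset({"WAT", "HOH", "SOL", "TIP3"}), "O")
CHLOROFORM_SELECTOR = SolventSelector(frozenset({"CL3", "CHL"}), "C")


@dataclass
class RadialDistribution:
    r_edges: np.ndarray
    g: np.ndarray
    raw_counts: np.ndarray
    bulk_density: float
    n_frames: int
    se: np.ndarray = field(default=None)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.r_edges[1] - self.r_edges[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_center": self.r_centers,
                "g": self.g,
                "raw_count": self.raw_counts,
                "se": self.se,
            }
        )


def _minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    return disp - box * np.round(disp / box)


def radial_solvent_distribution(
    trajectory: Trajectory,
    region: tuple[int, int],
    solvent_selector: SolventSelector = WATER_SELECTOR,
    bin_width: float = 0.5,
    r_max: float = 25.0,
) -> RadialDistribution:
    """Normalized radial distribution g(r) of solvent sites about the COM of
    an inclusive protein residue range.

    For a periodic frame ``r_max`` must not exceed half the shortest box
    edge (the minimum-image reach). A system without solvent yields g = 0
    everywhere with a warning.
    """
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    sites = solvent_selector.site_indices(trajectory)
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)

    volumes = []
    for frame in trajectory.frames:
        if frame.box is not None:
            if r_max > 0.5 * float(frame.box.min()):
                raise ValueError(
                    f"r_max={r_max} exceeds half the shortest box edge "
                    f"({0.5 * float(frame.box.min()):.2f} A)"
                )
            volumes.append(float(np.prod(frame.box)))
    if sites.size == 0:
        warnings.warn("no solvent molecules matched the selector; g is zero everywhere")
        return RadialDistribution(edges, np.zeros(n_bins), counts, 0.0, trajectory.n_frames, se=np.zeros(n_bins))
    if not volumes:
        raise ValueError("bulk normalization requires frames with a periodic box")

    for frame in trajectory.frames:
        com = center_of_mass(frame, trajectory.topology, region)
        disp = frame.coordinates[sites] - com
        if frame.box is not None:
            disp = _minimum_image(disp, frame.box)
        r = np.linalg.norm(disp, axis=1)
        r = r[r < r_max]
        counts += np.bincount((r / bin_width).astype(int), minlength=n_bins)[:n_bins]

    bulk = sites.size / float(np.mean(volumes))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = trajectory.n_frames * shell_vol * bulk
    g = counts / norm
    se = np.sqrt(counts) / norm
    return RadialDistribution(
        r_edges=edges,
        g=g,
        raw_counts=counts,
        bulk_density=bulk,
        n_frames=trajectory.n_frames,
        se=se,
    )


def compare_distributions(
    a: RadialDistribution, b: RadialDistribution
) -> pd.DataFrame:
    """Per-shell difference g_a - g_b with propagated Poisson uncertainty.

    The two distributions must share an identical shell grid.
    """
    if a.r_edges.shape != b.r_edges.shape or not np.allclose(a.r_edges, b.r_edges):
        raise ValueError("distributions are on different shell grids")
    diff = a.g - b.g
    se = np.sqrt(a.se**2 + b.se**2)
    return pd.DataFrame({"r_center": a.r_centers, "delta_g": diff, "se": se})
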