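"""Diagnostic residue separations and open/closed classification.

The saposin fold's flap geometry is tracked by two inter-helix separations:
d1 = TYR7-VAL34 (helix 1 to helix 2) and d2 = ILE45-VAL70 (helix 3 to
helix 4), plus the family-conserved CYS8-CYS35 distance. Frames are labelled
``open`` when both separations fall in the open band (default 20-40 A),
``closed`` when both fall in the closed band (12-17 A), ``partially_open``
when the helix-1/2 flap is closed while the helix-3/4 flap has separated, and
``other`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Topology, Trajectory, center_of_mass

__all__ = [
    "ClassificationRanges",
    "ConformationSeries",
    "DIAGNOSTIC_RESIDUES",
    "residue_separation",
    "classify_frame",
    "conformation_series",
    "state_fractions",
]

#: Residue pairs defining (d1, d2, d_cys), in mature-peptide numbering.
DIAGNOSTIC_RESIDUES = {"d1": (7, 34), "d2": (45, 70), "d_cys": (8, 35)}


@dataclass(frozen=True)
class ClassificationRanges:
    """Inclusive separation bands for the open and closed classes (Angstrom)."""

    open_range: tuple[float, float] = (20.0, 40.0)
    closed_range: tuple[float, float] = (12.0, 17.0)

    def __post_init__(self) -> None:
        o_lo, o_hi = self.open_range
        c_lo, c_hi = self.closed_range
        if not (o_lo < o_hi and c_lo < c_hi and c_hi <= o_lo):
            raise ValueError(
                "ranges must satisfy closed_low < closed_high <= open_low < open_high"
            )


@dataclass
class ConformationSeries:
    """Per-frame order parameters and class labels."""

    d1: np.ndarray
    d2: np.ndarray
    d_cys: np.ndarray
    labels: np.ndarray
    timestep: float = 1.0
    ranges: ClassificationRanges = field(default_factory=ClassificationRanges)

    @property
    def n_frames(self) -> int:
        return len(self.d1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_ns": np.arange(self.n_frames) * self.timestep,
                "d1": self.d1,
                "d2": self.d2,
                "d_cys": self.d_cys,
                "label": self.labels,
            }
        )


def _residue_centers(trajectory: Trajectory, residue: int, mode: str) -> np.ndarray:
    """(n_frames, 3) center positions of one residue."""
    top = trajectory.topology
    idx = top.residue_atom_indices(residue)
    coords = trajectory.coords_array()[:, idx, :]
    if mode == "com":
        m = top.masses[idx]
        return (m[None, :, None] * coords).sum(axis=1) / m.sum()
    if mode == "ca":
        for k, i in enumerate(idx):
            if top.atoms[i].name == "CA":
                return coords[:, k, :]
        raise ValueError(f"residue {residue} has no CA atom")
    raise ValueError(f"unknown separation mode {mode!r}")


def residue_separation(
    trajectory: Trajectory, res_a: int, res_b: int, mode: str = "com"
) -> np.ndarray:
    """Euclidean distance between two residue centers for every frame.

    ``mode='com'`` (default) uses each residue's center of mass, matching the
    distance masks of the trajectory tooling the analysis mirrors; ``'ca'``
    uses the alpha carbons.
    """
    known = {i for i, _ in trajectory.topology.residues}
    for r in (res_a, res_b):
        if r not in known:
            raise ValueError(f"residue {r} not present in topology")
    ca = _residue_centers(trajectory, res_a, mode)
    cb = _residue_centers(trajectory, res_b, mode)
    return np.linalg.norm(ca - cb, axis=1)


def classify_frame(
    d1: float, d2: float, ranges: ClassificationRanges | None = None
) -> str:
    """Label one frame from its (d1, d2) separations.

    Bounds are inclusive with closed-first precedence; ``partially_open``
    means the helix-1/2 flap is within the closed band while d2 exceeds it.
    """
    r = ranges or ClassificationRanges()
    c_lo, c_hi = r.closed_range
    o_lo, o_hi = r.open_range
    in_closed = lambda d: c_lo <= d <= c_hi  # noqa: E731
    in_open = lambda d: o_lo <= d <= o_hi  # noqa: E731
    if in_closed(d1) and in_closed(d2):
        return "closed"
    if in_open(d1) and in_open(d2):
        return "open"
    if in_closed(d1) and d2 > c_hi:
        return "partially_open"
    return "other"


def conformation_series(
    trajectory: Trajectory,
    ranges: ClassificationRanges | None = None,
    mode: str = "com",
) -> ConformationSeries:
    """Assemble d1, d2, d_cys and per-frame labels for a trajectory."""
    r = ranges or ClassificationRanges()
    d1 = residue_separation(trajectory, *DIAGNOSTIC_RESIDUES["d1"], mode=mode)
    d2 = residue_separation(trajectory, *DIAGNOSTIC_RESIDUES["d2"], mode=mode)
    d_cys = residue_separation(trajectory, *DIAGNOSTIC_RESIDUES["d_cys"], mode=mode)
    labels = np.array([classify_frame(a, b, r) for a, b in zip(d1, d2)])
    return ConformationSeries(
        d1=d1, d2=d2, d_cys=d_cys, labels=labels, timestep=trajectory.timestep, ranges=r
    )


def state_fractions(series: ConformationSeries) -> dict[str, float]:
    """Fraction of frames carrying each class label."""
    labels, counts = np.unique(series.labels, return_counts=True)
    total = counts.sum()
    out = {lab: 0.0 for lab in ("open", "closed", "partially_open", "other")}
    out.update({str(l): float(c) / total for l, c in zip(labels, counts)})
    return out
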