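"""Two-distance free-energy landscapes by Boltzmann inversion.

The (d1, d2) time series is binned on a uniform grid (default width 0.1 A,
edges anchored at integer multiples of the width so bin identity does not
depend on the data), frame counts are pooled over replicates into state
probabilities P_i, and the relative free energy of each occupied state is

    dG_i = -R T ln P_i   (R = 1.9872e-3 kcal/mol/K, T = 310 K by default)

shifted so the most probable occupied state sits at zero. Unoccupied bins are
left undefined (NaN with an occupancy mask) rather than infinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conformation import ConformationSeries
from .structure import Trajectory

__all__ = [
    "ThermoParams",
    "FreeEnergyLandscape",
    "select_window",
    "bin_states",
    "pool_counts",
    "free_energy",
    "find_minima",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class ThermoParams:
    R: float = R_KCAL
    T: float = 310.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class BinnedStates:
    """2D frame-count histogram on anchored half-open bins [edge, edge+w)."""

    counts: np.ndarray
    d1_edges: np.ndarray
    d2_edges: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.d1_edges[1] - self.d1_edges[0])


@dataclass
class FreeEnergyLandscape:
    d1_edges: np.ndarray
    d2_edges: np.ndarray
    counts: np.ndarray
    P: np.ndarray
    dG: np.ndarray
    occupied_mask: np.ndarray

    @property
    def d1_centers(self) -> np.ndarray:
        return 0.5 * (self.d1_edges[:-1] + self.d1_edges[1:])

    @property
    def d2_centers(self) -> np.ndarray:
        return 0.5 * (self.d2_edges[:-1] + self.d2_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        i, j = np.nonzero(self.occupied_mask)
        return pd.DataFrame(
            {
                "d1_center": self.d1_centers[i],
                "d2_center": self.d2_centers[j],
                "count": self.counts[i, j],
                "P": self.P[i, j],
                "dG": self.dG[i, j],
            }
        ).sort_values("dG", ignore_index=True)


def select_window(obj, last_duration: float):
    """Keep only the final ``last_duration`` ns of a trajectory or series,
    discarding the earlier (equilibration) portion."""
    if last_duration <= 0:
        raise ValueError("window duration must be positive")
    if isinstance(obj, Trajectory):
        n, dt = obj.n_frames, obj.timestep
    elif isinstance(obj, ConformationSeries):
        n, dt = obj.n_frames, obj.timestep
    else:
        raise TypeError("select_window expects a Trajectory or ConformationSeries")
    total = n * dt
    if total < last_duration:
        raise ValueError(
            f"series spans {total:g} ns, shorter than the {last_duration:g} ns window; "
            "use the full series instead"
        )
    n_keep = min(n, int(round(last_duration / dt)))
    if isinstance(obj, Trajectory):
        return Trajectory(obj.topology, obj.frames[n - n_keep :], dt)
    return ConformationSeries(
        d1=obj.d1[n - n_keep :],
        d2=obj.d2[n - n_keep :],
        d_cys=obj.d_cys[n - n_keep :],
        labels=obj.labels[n - n_keep :],
        timestep=dt,
        ranges=obj.ranges,
    )


def bin_states(d1_series, d2_series, bin_width: float = 0.1) -> BinnedStates:
    """2D histogram of the two separations on half-open anchored bins."""
    d1 = np.asarray(d1_series, dtype=float)
    d2 = np.asarray(d2_series, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("d1 and d2 series must have equal length")
    if d1.size == 0:
        raise ValueError("cannot bin an empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    i1 = np.floor(d1 / bin_width).astype(int)
    i2 = np.floor(d2 / bin_width).astype(int)
    o1, o2 = i1.min(), i2.min()
    n1 = i1.max() - o1 + 1
    n2 = i2.max() - o2 + 1
    counts = np.zeros((n1, n2), dtype=np.int64)
    np.add.at(counts, (i1 - o1, i2 - o2), 1)
    d1_edges = (np.arange(n1 + 1) + o1) * bin_width
    d2_edges = (np.arange(n2 + 1) + o2) * bin_width
    return BinnedStates(counts=counts, d1_edges=d1_edges, d2_edges=d2_edges)


def pool_counts(replicates: list[BinnedStates]) -> BinnedStates:
    """Sum replicate count grids on a common anchored grid.

    All replicates must share the bin width; the pooled grid is the union of
    their extents (anchoring makes bin identity data-independent).
    """
    if not replicates:
        raise ValueError("no replicates to pool")
    w = replicates[0].bin_width
    for b in replicates:
        if not np.isclose(b.bin_width, w):
            raise ValueError("replicates have mismatched bin widths")
    o1 = min(int(round(b.d1_edges[0] / w)) for b in replicates)
    o2 = min(int(round(b.d2_edges[0] / w)) for b in replicates)
    e1 = max(int(round(b.d1_edges[-1] / w)) for b in replicates)
    e2 = max(int(round(b.d2_edges[-1] / w)) for b in replicates)
    counts = np.zeros((e1 - o1, e2 - o2), dtype=np.int64)
    for b in replicates:
        s1 = int(round(b.d1_edges[0] / w)) - o1
        s2 = int(round(b.d2_edges[0] / w)) - o2
        counts[s1 : s1 + b.counts.shape[0], s2 : s2 + b.counts.shape[1]] += b.counts
    return BinnedStates(
        counts=counts,
        d1_edges=(np.arange(e1 - o1 + 1) + o1) * w,
        d2_edges=(np.arange(e2 - o2 + 1) + o2) * w,
    )


def free_energy(
    binned: BinnedStates, thermo: ThermoParams | None = None
) -> FreeEnergyLandscape:
    """Boltzmann-invert pooled state counts into a relative free-energy grid."""
    thermo = thermo or ThermoParams()
    counts = np.asarray(binned.counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total frame count must be positive")
    P = counts / total
    occupied = counts > 0
    dG = np.full(P.shape, np.nan)
    dG[occupied] = -thermo.RT * np.log(P[occupied])
    dG[occupied] -= dG[occupied].min()
    return FreeEnergyLandscape(
        d1_edges=binned.d1_edges,
        d2_edges=binned.d2_edges,
        counts=counts,
        P=P,
        dG=dG,
        occupied_mask=occupied,
    )


_NEIGHBORHOODS = {
    "4-connected": [(-1, 0), (1, 0), (0, -1), (0, 1)],
    "8-connected": [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)],
}


def find_minima(
    landscape: FreeEnergyLandscape, neighborhood: str = "8-connected"
) -> list[tuple[float, float, float]]:
    """Occupied bins whose dG is strictly below every occupied neighbor,
    sorted ascending by dG."""
    try:
        offsets = _NEIGHBORHOODS[neighborhood]
    except KeyError:
        raise ValueError("neighborhood must be '4-connected' or '8-connected'") from None
    dG = landscape.dG
    occ = landscape.occupied_mask
    n1, n2 = dG.shape
    minima = []
    for i, j in zip(*np.nonzero(occ)):
        is_min = True
        for di, dj in offsets:
            a, b = i + di, j + dj
            if 0 <= a < n1 and 0 <= b < n2 and occ[a, b] and dG[a, b] <= dG[i, j]:
                is_min = False
                break
        if is_min:
            minima.append(
                (float(landscape.d1_centers[i]), float(landscape.d2_centers[j]), float(dG[i, j]))
            )
    minima.sort(key=lambda t: t[2])
    return minima
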