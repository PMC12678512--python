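"""k-means clustering of trajectory frames under a superposition metric.

True pairwise-RMSD k-means is ill-posed (RMSD is not a Euclidean metric on
conformations), so the standard surrogate is used: every frame is rigidly
superposed onto the trajectory's iterated average structure on the chosen
atom selection, and the flattened superposed coordinates are clustered with
Lloyd's algorithm (k-means++ seeding, best of ``n_init`` restarts). For
frames near a common reference this Euclidean distance approximates the
pairwise RMSD, reproducing the practical behaviour of RMSD-metric clustering
of MD frames. Clusters are reported in descending size order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .conformation import ConformationSeries
from .structure import Trajectory
from .superpose import BACKBONE_ATOMS, average_structure, kabsch_superpose

__all__ = ["ClusterResult", "kmeans_frames", "project_representatives"]


@dataclass
class ClusterResult:
    labels: np.ndarray
    sizes: np.ndarray
    centers: np.ndarray
    representatives: np.ndarray
    inertia: float
    selection_indices: np.ndarray

    @property
    def k(self) -> int:
        return len(self.sizes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.labels)), "cluster": self.labels})


def kmeans_frames(
    trajectory: Trajectory,
    k: int = 5,
    selection: set[str] | None = BACKBONE_ATOMS,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterResult:
    """Cluster frames by k-means on globally superposed selected coordinates.

    Clusters are relabelled in descending size order; ``representatives[c]``
    is the index of the member frame closest to cluster c's center.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > trajectory.n_frames:
        raise ValueError(
            f"k={k} exceeds the number of frames ({trajectory.n_frames})"
        )
    top = trajectory.topology
    sel = top.select(set(selection) if selection is not None else None, protein_only=True)
    if sel.size == 0:
        raise ValueError("selection matches no atoms")
    weights = top.masses[sel]

    avg = average_structure(trajectory, selection=selection)
    coords = trajectory.coords_array()[:, sel, :]
    ref = avg.coordinates[sel]
    for f in range(coords.shape[0]):
        res = kabsch_superpose(coords[f], ref, weights)
        coords[f] = res.transform(coords[f])
    X = coords.reshape(coords.shape[0], -1)

    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    raw_labels = km.fit_predict(X)

    order = np.argsort(-np.bincount(raw_labels, minlength=k), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw_labels]
    sizes = np.bincount(labels, minlength=k)
    centers = km.cluster_centers_[order].reshape(k, -1, 3)

    representatives = np.full(k, -1, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:  # degenerate data can leave a cluster empty
            continue
        d = np.linalg.norm(X[members] - centers[c].reshape(-1), axis=1)
        representatives[c] = members[np.argmin(d)]

    return ClusterResult(
        labels=labels,
        sizes=sizes,
        centers=centers,
        representatives=representatives,
        inertia=float(km.inertia_),
        selection_indices=sel,
    )


def project_representatives(
    result: ClusterResult, series: ConformationSeries
) -> list[tuple[float, float]]:
    """(d1, d2) of each cluster's representative frame, largest cluster first
    (NaNs for a cluster that ended up empty)."""
    if series.n_frames < len(result.labels):
        raise ValueError("series does not cover the clustered frames")
    return [
        (float(series.d1[f]), float(series.d2[f])) if f >= 0 else (np.nan, np.nan)
        for f in result.representatives
    ]
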