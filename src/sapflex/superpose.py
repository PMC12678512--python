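"""Rigid-body superposition and the fluctuation statistics built on it.

The optimal rotation is obtained by the Kabsch procedure (SVD of the weighted
cross-covariance, with the reflection branch excluded), which minimizes the
mass-weighted RMSD

    RMSD = sqrt( sum_a w_a |R x_a + t - y_a|^2 / sum_a w_a ).

Per-residue RMSF follows the two-pass scheme: an iterated average structure is
computed first, every frame is then superposed onto it, and the mass-weighted
fluctuation of each residue's atoms about their mean positions is reported.
High-flexibility (hinge) regions are the maximal runs of residues whose RMSF
exceeds the profile mean plus one standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Frame, Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "FlexibilityProfile",
    "kabsch_superpose",
    "rmsd_series",
    "average_structure",
    "rmsf_per_residue",
    "flexibility_profile",
    "find_flexible_regions",
    "BACKBONE_ATOMS",
]

#: Default "peptide backbone" selection.
BACKBONE_ATOMS = frozenset({"N", "CA", "C"})


@dataclass
class SuperpositionResult:
    """Optimal rigid transform ``x -> x @ rotation.T + translation`` and the
    residual weighted RMSD (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class FlexibilityProfile:
    residue_indices: np.ndarray
    per_residue_rmsf: np.ndarray
    mean: float
    sd: float
    threshold: float
    peak_regions: list[tuple[int, int]]


def _validate_weights(n: int, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum, one per atom")
    return w


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Optimal weighted rigid-body superposition of ``mobile`` onto
    ``reference``.

    Requires at least 3 non-collinear points; the returned rotation always has
    determinant +1 (proper rotation, no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    w = _validate_weights(n, weights)
    wn = w / w.sum()

    mu_m = wn @ mobile
    mu_r = wn @ reference
    x = mobile - mu_m
    y = reference - mu_r

    cov = x.T @ (y * wn[:, None])
    u, s, vt = np.linalg.svd(cov)
    # collinear/degenerate geometry leaves the rotation underdetermined
    xs = np.linalg.svd(x * np.sqrt(wn)[:, None], compute_uv=False)
    if xs[1] < 1e-9 * max(xs[0], 1.0):
        raise ValueError("degenerate (collinear) geometry: rotation is underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = mu_r - rotation @ mu_m

    moved = x @ rotation.T
    rmsd = float(np.sqrt(np.sum(wn * np.sum((moved - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _selection_indices(topology: Topology, selection: set[str] | frozenset[str] | None) -> np.ndarray:
    sel = topology.select(set(selection) if selection is not None else None, protein_only=True)
    if sel.size == 0:
        raise ValueError(f"selection {sorted(selection or [])} matches no atoms")
    return sel


def rmsd_series(
    trajectory: Trajectory,
    reference: Frame,
    selection: set[str] | None = BACKBONE_ATOMS,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Superposed RMSD of every frame against ``reference`` on the selected
    atoms (default: peptide backbone N, CA, C)."""
    sel = _selection_indices(trajectory.topology, selection)
    w = trajectory.topology.masses[sel] if mass_weighted else None
    ref = reference.coordinates[sel]
    return np.array(
        [kabsch_superpose(f.coordinates[sel], ref, w).rmsd for f in trajectory.frames]
    )


def average_structure(
    trajectory: Trajectory,
    selection: set[str] | None = BACKBONE_ATOMS,
    max_iter: int = 10,
    tol: float = 1e-4,
    mass_weighted: bool = True,
) -> Frame:
    """Iterated mean structure: align all frames to the current average on the
    selection, recompute the mean of all atoms, and repeat until the average
    moves less than ``tol`` (Angstrom, RMS over selected atoms)."""
    top = trajectory.topology
    sel = _selection_indices(top, selection)
    w = top.masses[sel] if mass_weighted else None
    coords = trajectory.coords_array()
    avg = coords[0].copy()
    for _ in range(max_iter):
        aligned = np.empty_like(coords)
        for k in range(coords.shape[0]):
            res = kabsch_superpose(coords[k, sel], avg[sel], w)
            aligned[k] = res.transform(coords[k])
        new_avg = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_avg[sel] - avg[sel]) ** 2, axis=1))))
        avg = new_avg
        if shift < tol:
            break
    return Frame(avg)


def rmsf_per_residue(
    trajectory: Trajectory,
    average: Frame | None = None,
    selection: set[str] | None = BACKBONE_ATOMS,
    align: bool = True,
) -> FlexibilityProfile:
    """Mass-weighted per-residue RMSF over the trajectory.

    Each frame is first superposed onto ``average`` on the selection (computed
    internally when not supplied); with ``align=False`` raw coordinates are
    used, which is the convention under which i.i.d. Gaussian noise of
    per-coordinate sigma gives a flat profile at sigma*sqrt(3).
    """
    top = trajectory.topology
    sel = _selection_indices(top, selection)
    if average is None:
        average = average_structure(trajectory, selection=selection)
    w_sel = top.masses[sel]
    coords = trajectory.coords_array()
    if align:
        for k in range(coords.shape[0]):
            res = kabsch_superpose(coords[k, sel], average.coordinates[sel], w_sel)
            coords[k] = res.transform(coords[k])
    mean_pos = coords.mean(axis=0)
    msd_atom = np.mean(np.sum((coords - mean_pos[None]) ** 2, axis=2), axis=0)

    res_of_sel = top.residue_indices[sel]
    masses = top.masses[sel]
    residue_ids = np.array([i for i, _ in top.protein_residues()])
    rmsf = np.full(residue_ids.shape, np.nan)
    for j, rid in enumerate(residue_ids):
        mask = res_of_sel == rid
        if not mask.any():
            continue
        m = masses[mask]
        rmsf[j] = np.sqrt(np.sum(m * msd_atom[sel[mask]]) / m.sum())
    return flexibility_profile(residue_ids, rmsf)


def flexibility_profile(residue_indices: np.ndarray, rmsf: np.ndarray) -> FlexibilityProfile:
    """Build a profile from per-residue RMSF values: the peak threshold is the
    profile mean plus one standard deviation; residues with no RMSF (no
    selected atoms) are NaN and excluded from the statistics."""
    rmsf = np.asarray(rmsf, dtype=float)
    valid = ~np.isnan(rmsf)
    mean = float(np.mean(rmsf[valid]))
    sd = float(np.std(rmsf[valid]))
    profile = FlexibilityProfile(
        residue_indices=np.asarray(residue_indices, dtype=int),
        per_residue_rmsf=rmsf,
        mean=mean,
        sd=sd,
        threshold=mean + sd,
        peak_regions=[],
    )
    profile.peak_regions = find_flexible_regions(profile)
    return profile


def find_flexible_regions(profile: FlexibilityProfile) -> list[tuple[int, int]]:
    """Maximal contiguous residue runs with RMSF strictly above mean + sd."""
    above = profile.per_residue_rmsf > profile.threshold
    regions: list[tuple[int, int]] = []
    start = None
    ids = profile.residue_indices
    for i, flag in enumerate(above):
        if flag and not np.isnan(profile.per_residue_rmsf[i]):
            if start is None:
                start = ids[i]
            end = ids[i]
        elif start is not None:
            regions.append((int(start), int(end)))
            start = None
    if start is not None:
        regions.append((int(start), int(end)))
    return regions
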