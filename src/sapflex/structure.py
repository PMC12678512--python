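"""Core in-memory model of a protein system: atoms, topology, frames, trajectories.

Coordinates are in Angstrom throughout; residue numbering is 1-based so that it
matches the mature-peptide numbering used in the saposin literature (TYR7 is the
7th residue of the chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "ATOMIC_MASSES",
    "SOLVENT_RESIDUE_NAMES",
    "guess_element",
    "atomic_mass",
    "center_of_mass",
    "detect_disulfides",
]

# Standard atomic masses (Da), sufficient for proteins plus the solvent and
# counterion species handled here.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "CL": 35.45,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "SE": 78.971,
}

#: Residue names recognized as solvent rather than protein.
SOLVENT_RESIDUE_NAMES = frozenset({"WAT", "HOH", "CL3", "CHL", "SOL", "TIP3"})

_TWO_LETTER_ELEMENTS = ("CL", "NA", "MG", "FE", "ZN", "SE", "BR")


def guess_element(atom_name: str, residue_name: str = "") -> str:
    """Infer the element symbol from a PDB atom name.

    Within amino-acid residues the first alphabetic character is the element
    (``CA`` is an alpha carbon, not calcium); two-letter element names are only
    considered for non-protein residues such as ions and solvent.
    """
    name = atom_name.strip().lstrip("0123456789").upper()
    if not name:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    resname = residue_name.strip().upper()
    is_protein = resname not in SOLVENT_RESIDUE_NAMES and resname not in ("CL-", "NA+", "CL", "NA", "K+", "MG", "ION")
    if not is_protein and name[:2] in _TWO_LETTER_ELEMENTS:
        return name[:2]
    return name[0]


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no standard mass for element {element!r}") from None


@dataclass
class Atom:
    """A single atom: identity plus (optionally) its first-model coordinates."""

    name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive, got {self.mass}")


@dataclass
class Topology:
    """Static chemical identity of the system.

    ``residues`` is an ordered list of ``(index, three_letter_code)`` with
    strictly increasing 1-based indices; ``atoms`` lists every atom in file
    order.
    """

    residues: list[tuple[int, str]]
    atoms: list[Atom]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        indices = [i for i, _ in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("residue indices must be strictly increasing")
        known = set(indices)
        for atom in self.atoms:
            if atom.residue_index not in known:
                raise ValueError(
                    f"atom {atom.name} references residue {atom.residue_index} not present in topology"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def residue_indices(self) -> np.ndarray:
        """Per-atom residue index array."""
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def residue_name(self, residue_index: int) -> str:
        for idx, name in self.residues:
            if idx == residue_index:
                return name
        raise KeyError(f"residue {residue_index} not in topology")

    def select(self, atom_names: set[str] | None = None, protein_only: bool = False) -> np.ndarray:
        """Indices of atoms whose name is in ``atom_names`` (all atoms if None)."""
        idx = []
        for i, atom in enumerate(self.atoms):
            if protein_only and atom.residue_name.upper() in SOLVENT_RESIDUE_NAMES:
                continue
            if atom_names is None or atom.name in atom_names:
                idx.append(i)
        return np.array(idx, dtype=int)

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        idx = [i for i, a in enumerate(self.atoms) if a.residue_index == residue_index]
        if not idx:
            raise KeyError(f"residue {residue_index} has no atoms in topology")
        return np.array(idx, dtype=int)

    def protein_residues(self) -> list[tuple[int, str]]:
        return [(i, n) for i, n in self.residues if n.upper() not in SOLVENT_RESIDUE_NAMES]


@dataclass
class Frame:
    """One time point: an (n_atoms, 3) coordinate array plus an optional
    orthorhombic box given as three edge lengths."""

    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box edge lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered frame sequence over a fixed topology.

    ``timestep`` is the time between consecutive frames in ns.
    """

    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    timestep: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, frame in enumerate(self.frames):
            if frame.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {frame.n_atoms} atoms but topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Total simulated time spanned by the frames (ns)."""
        return self.n_frames * self.timestep

    def coords_array(self) -> np.ndarray:
        """All coordinates as a (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])

    def __getitem__(self, key) -> "Trajectory":
        if isinstance(key, int):
            key = slice(key, key + 1 if key != -1 else None)
        frames = self.frames[key]
        if not frames:
            raise IndexError("slice selects no frames")
        return Trajectory(self.topology, list(frames), self.timestep)


def center_of_mass(
    frame: Frame, topology: Topology, residue_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Mass-weighted mean position of all atoms in the inclusive residue range
    (whole system if ``residue_range`` is None)."""
    if residue_range is None:
        idx = np.arange(topology.n_atoms)
    else:
        lo, hi = residue_range
        res_idx = topology.residue_indices
        idx = np.flatnonzero((res_idx >= lo) & (res_idx <= hi))
        if idx.size == 0:
            raise ValueError(f"residue range {lo}-{hi} selects no atoms")
    m = topology.masses[idx]
    x = frame.coordinates[idx]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def detect_disulfides(
    frame: Frame, topology: Topology, cutoff: float = 2.5
) -> list[tuple[int, int]]:
    """Cysteine SG-SG pairs closer than ``cutoff`` Angstrom.

    Pairing is greedy nearest-first and each SG participates in at most one
    bond; pairs are reported with the lower residue index first, sorted.
    A CYS residue lacking an SG atom is skipped with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sg = {}
    cys_residues = [i for i, name in topology.residues if name.upper() == "CYS"]
    for i, atom in enumerate(topology.atoms):
        if atom.residue_name.upper() == "CYS" and atom.name == "SG":
            sg[atom.residue_index] = i
    for r in cys_residues:
        if r not in sg:
            warnings.warn(f"CYS {r} has no SG atom; skipped in disulfide search")
    residues = sorted(sg)
    if len(residues) < 2:
        return []
    pos = np.array([frame.coordinates[sg[r]] for r in residues])
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    candidates = [
        (dist[i, j], residues[i], residues[j])
        for i in range(len(residues))
        for j in range(i + 1, len(residues))
        if dist[i, j] < cutoff
    ]
    candidates.sort()
    used: set[int] = set()
    pairs = []
    for _, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        pairs.append((min(a, b), max(a, b)))
    return sorted(pairs)
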