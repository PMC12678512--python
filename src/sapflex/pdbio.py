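"""Reading and writing multi-model PDB files and the plain per-frame
coordinate-table format used for long synthetic trajectories.

PDB parsing and formatting are delegated to biotite; this module adapts the
result to the package's :class:`~sapflex.structure.Topology` /
:class:`~sapflex.structure.Trajectory` types and enforces the multi-model
contract (every MODEL must contain the same atoms, in the same order).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .sequence import THREE_TO_ONE
from .structure import (
    Atom,
    Frame,
    SOLVENT_RESIDUE_NAMES,
    Topology,
    Trajectory,
    atomic_mass,
    guess_element,
)

__all__ = [
    "PDBParseError",
    "read_pdb_models",
    "write_pdb_models",
    "read_coord_table",
    "write_coord_table",
]

_KNOWN_RESIDUES = set(THREE_TO_ONE) | SOLVENT_RESIDUE_NAMES | {"CL-", "NA+", "CL", "NA", "K+"}


class PDBParseError(ValueError):
    """Raised when a PDB file violates the multi-model trajectory contract."""


def _check_model_atom_counts(path: Path) -> None:
    """Pre-scan MODEL blocks; raise naming the first model whose atom count
    differs from model 1."""
    counts: list[tuple[int, int]] = []
    model, n = None, 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                model = int(line.split()[1]) if len(line.split()) > 1 else (len(counts) + 1)
                n = 0
            elif rec.startswith(("ATOM", "HETATM")):
                n += 1
            elif rec.startswith("ENDMDL"):
                counts.append((model if model is not None else len(counts) + 1, n))
                model = None
    if model is not None or (not counts and n > 0):
        counts.append((model if model is not None else 1, n))
    if len(counts) > 1:
        ref = counts[0][1]
        for model_id, count in counts[1:]:
            if count != ref:
                raise PDBParseError(
                    f"model {model_id} has {count} atoms but model {counts[0][0]} has {ref}"
                )


def read_pdb_models(path: str | Path, timestep: float = 1.0) -> Trajectory:
    """Read a (possibly multi-model) PDB file as a trajectory.

    The topology is taken from the first model; one frame is produced per
    MODEL record (a single unlabeled model yields a one-frame trajectory).
    Unknown residue codes are retained with a warning and an element inferred
    from the atom name. Orthorhombic CRYST1 boxes are attached to every frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_model_atom_counts(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # pragma: no cover - count mismatch is caught above
        raise PDBParseError(f"failed to parse {path.name}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    atoms: list[Atom] = []
    residues: list[tuple[int, str]] = []
    seen: set[int] = set()
    first = stack[0]
    unknown: set[str] = set()
    for i in range(stack.array_length()):
        res_id = int(first.res_id[i])
        res_name = str(first.res_name[i]).strip()
        if res_id not in seen:
            seen.add(res_id)
            residues.append((res_id, res_name))
        if res_name.upper() not in _KNOWN_RESIDUES:
            unknown.add(res_name)
        element = str(first.element[i]).strip() or guess_element(str(first.atom_name[i]), res_name)
        try:
            mass = atomic_mass(element)
        except KeyError:
            element = guess_element(str(first.atom_name[i]), res_name)
            mass = atomic_mass(element)
        atoms.append(
            Atom(
                name=str(first.atom_name[i]).strip(),
                element=element,
                mass=mass,
                residue_index=res_id,
                residue_name=res_name,
                coordinates=np.array(first.coord[i], dtype=float),
            )
        )
    for name in sorted(unknown):
        warnings.warn(f"unknown residue code {name!r}; atoms retained with inferred elements")

    chain_id = str(first.chain_id[0]) if stack.array_length() else "A"
    topology = Topology(residues=residues, atoms=atoms, chain_id=chain_id or "A")

    frames = []
    for m in range(stack.stack_depth()):
        box = None
        if stack.box is not None:
            vectors = stack.box[m]
            edges = np.linalg.norm(vectors, axis=1)
            if np.all(edges > 0):
                box = edges
        frames.append(Frame(np.array(stack.coord[m], dtype=float), box=box))
    return Trajectory(topology=topology, frames=frames, timestep=timestep)


def write_pdb_models(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL dialect)."""
    top = trajectory.topology
    n = top.n_atoms
    array = struc.AtomArray(n)
    array.coord = trajectory.frames[0].coordinates.astype(np.float32)
    array.chain_id = np.full(n, top.chain_id)
    array.res_id = top.residue_indices
    array.res_name = np.array([a.residue_name for a in top.atoms])
    array.atom_name = np.array([a.name for a in top.atoms])
    array.element = np.array([a.element for a in top.atoms])
    array.hetero = np.array(
        [a.residue_name.upper() in SOLVENT_RESIDUE_NAMES for a in top.atoms]
    )
    stack = struc.stack([array] * trajectory.n_frames)
    stack.coord = trajectory.coords_array().astype(np.float32)
    box = trajectory.frames[0].box
    if box is not None:
        stack.box = np.repeat(np.diag(box)[None, :, :], trajectory.n_frames, axis=0)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_coord_table(trajectory: Trajectory, path: str | Path) -> None:
    """Write the whitespace-delimited per-frame coordinate table
    (columns: frame, atom, x, y, z; 0-based frame and atom ordinals)."""
    coords = trajectory.coords_array()
    n_frames, n_atoms, _ = coords.shape
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    atom_col = np.tile(np.arange(n_atoms), n_frames)
    flat = coords.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame": frame_col,
            "atom": atom_col,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    )
    df.to_csv(path, sep=" ", index=False, float_format="%.4f")


def read_coord_table(
    path: str | Path, topology: Topology, timestep: float = 1.0, box: np.ndarray | None = None
) -> Trajectory:
    """Read a coordinate table written by :func:`write_coord_table` against a
    known topology."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise PDBParseError(f"coordinate table must have columns {sorted(required)}")
    n_atoms = topology.n_atoms
    frames = []
    for frame_id, group in df.groupby("frame", sort=True):
        group = group.sort_values("atom")
        if len(group) != n_atoms:
            raise PDBParseError(
                f"frame {frame_id} has {len(group)} atoms but topology has {n_atoms}"
            )
        frames.append(Frame(group[["x", "y", "z"]].to_numpy(float), box=box))
    return Trajectory(topology=topology, frames=frames, timestep=timestep)
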