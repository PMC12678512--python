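"""Ground-truth synthetic trajectories of a two-flap saposin-like hinge protein.

The generator builds a backbone-only (N, CA, C, O) 79-residue model with four
ideal alpha-helical segments at the fold's conserved regions (9-19, 27-33,
46-61, 69-72) joined by coiled linkers, plus SG pseudo-atoms on the seven
cysteines arranged so the three saposin disulfides (8-77, 11-71, 35-46) are
detectable. The two flaps (helices 1+4 with the termini, versus helices 2+3)
hinge about a fixed axis; the flap orientation is solved numerically so that
the measured TYR7-VAL34 and ILE45-VAL70 separations match the requested
closed and open geometries to within 0.5 A.

Trajectories are produced by a two-state Markov chain over the open/closed
reference geometries with i.i.d. isotropic Gaussian positional noise, which
gives closed-form expectations for every downstream statistic (stationary
occupancies, RMSF of sigma*sqrt(3) without alignment, landscape basin
probabilities). A uniform-density single-site solvent in a periodic cubic box
provides the radial-distribution ground truth. All randomness flows from the
single seed in the parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .builder import ideal_alpha_helix
from .sequence import SPB_MATURE_SEQUENCE, THREE_TO_ONE
from .structure import Atom, Frame, Topology, Trajectory, atomic_mass

__all__ = [
    "HingeModelParams",
    "GroundTruth",
    "HELIX_REGIONS",
    "DISULFIDE_PAIRS",
    "build_hinge_protein",
    "simulate_hinge_trajectory",
    "add_uniform_solvent",
    "spb_standin_models",
]

#: Conserved helical regions of the fold (inclusive residue ranges).
HELIX_REGIONS = ((9, 19), (27, 33), (46, 61), (69, 72))
#: The three saposin disulfide bonds.
DISULFIDE_PAIRS = ((8, 77), (11, 71), (35, 46))
_FREE_CYS = 48
_DIAGNOSTIC = (7, 34, 45, 70)

_CANDIDATE_DIRECTIONS = np.array(
    [v / np.linalg.norm(v) for v in __import__("itertools").product((-1.0, 0.0, 1.0), repeat=3) if any(v)]
)

_ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}

# fixed scaffold geometry (Angstrom): helix-axis start anchors and directions
_ANCHOR = {
    "H1": ((-4.0, 2.5, 0.0), (0.0, 1.0, 0.0)),
    "H2": ((-3.0, 21.0, 5.5), (0.0, -1.0, 0.0)),
    "H3": ((2.5, 1.0, 5.5), (0.0, 1.0, 0.0)),
    "H4": ((3.0, 12.5, 0.0), (0.0, -1.0, 0.0)),
}
_HINGE_POINT = np.array([0.0, 26.0, 2.75])
_RISE = 1.5  # alpha-helix rise per residue along the axis
_SPACING = 3.5  # target consecutive-CA distance in linkers

# linker routing parameters, chosen for inter-segment clearance in both the
# closed and the open pose: the cross-hinge linkers are compact coils bowed
# away from the helix bundle (helix 1/2 side toward -x, helix 3/4 toward +x)
_L1_NORMAL = (-1.0, 0.8, -0.3)
_L1_TURNS = 0.8
_L1_BOW = 6.0
_L3_NORMAL = (1.0, 0.5, 0.0)
_L3_TURNS = 0.8
_L3_BOW = 6.0
_TAIL_APPROACH = (1.2, -0.8, 0.6)
_TAIL_BEND = (0.3, -0.6, 0.4)
_NTERM_DIR = (-0.9, -1.1, -0.3)
_NTERM_NORMAL = (0.2, 0.3, -1.0)


@dataclass
class HingeModelParams:
    """Conditions of the synthetic two-state hinge system.

    The closed and open (d1, d2) targets default to the representative
    starting-model separations of the fold: closed (15, 14) A, open
    (25, 27) A, inside the classification bands 12-17 and 20-40 A.
    """

    n_residues: int = 79
    closed_geometry: tuple[float, float] = (15.0, 14.0)
    open_geometry: tuple[float, float] = (25.0, 27.0)
    noise_sigma: float = 0.75
    rate_open_to_closed: float = 0.01
    rate_closed_to_open: float = 0.01
    n_frames: int = 1000
    timestep: float = 1.0
    seed: int = 0
    start_state: str = "closed"

    def __post_init__(self) -> None:
        if self.n_residues < 12:
            raise ValueError("hinge model needs at least 12 residues")
        for r in (self.rate_open_to_closed, self.rate_closed_to_open):
            if not 0.0 <= r <= 1.0:
                raise ValueError("switch rates must be probabilities in [0, 1]")
        for d in self.closed_geometry:
            if not 12.0 <= d <= 17.0:
                raise ValueError("closed geometry must lie in the closed band 12-17 A")
        for d in self.open_geometry:
            if not 20.0 <= d <= 40.0:
                raise ValueError("open geometry must lie in the open band 20-40 A")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.start_state not in ("open", "closed"):
            raise ValueError("start_state must be 'open' or 'closed'")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    state_sequence: np.ndarray
    stationary_occupancy: tuple[float, float]  # (pi_open, pi_closed)
    reference_geometries: dict[str, Frame] = field(default_factory=dict)


def _scaled_layout(n_residues: int) -> dict:
    s = n_residues / 79.0
    scale = lambda r: int(min(n_residues, max(1, round(r * s))))  # noqa: E731
    helices = []
    prev_end = 0
    for a, b in HELIX_REGIONS:
        a2, b2 = scale(a), scale(b)
        a2 = max(a2, prev_end + 2)
        b2 = max(b2, a2 + 1)
        if b2 > n_residues:
            raise ValueError(f"{n_residues} residues cannot host four helical segments")
        helices.append((a2, b2))
        prev_end = b2
    if helices[-1][1] > n_residues - 1:
        raise ValueError(f"{n_residues} residues leave no room for a C-terminal linker")
    diag = tuple(scale(r) for r in _DIAGNOSTIC)
    if n_residues == 79:
        sequence = SPB_MATURE_SEQUENCE
        cys_pairs = DISULFIDE_PAIRS
        free_cys = _FREE_CYS
    else:
        sequence = "A" * n_residues
        cys_pairs, free_cys = (), None
    return {
        "helices": helices,
        "diag": diag,
        "sequence": sequence,
        "cys_pairs": cys_pairs,
        "free_cys": free_cys,
    }


def _fit_helix(n_res: int, anchor: tuple, rng_phase: float = 0.0) -> dict[str, np.ndarray]:
    """Build an ideal helix and rigidly place it on an axis anchor."""
    start, direction = (np.asarray(a, dtype=float) for a in anchor)
    direction = direction / np.linalg.norm(direction)
    helix = ideal_alpha_helix(n_res)
    ca = helix["CA"]
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, vt = np.linalg.svd(centered)
    u = vt[0]
    if np.dot(u, ca[-1] - ca[0]) < 0:
        u = -u
    s = centered @ u
    axis_start = centroid + s.min() * u
    rot, _ = Rotation.align_vectors(direction[None, :], u[None, :])
    if rng_phase:
        rot = Rotation.from_rotvec(rng_phase * direction) * rot
    return {
        k: rot.apply(v - axis_start) + start for k, v in helix.items()
    }


def _coil_path(
    p0: np.ndarray,
    p1: np.ndarray,
    n_points: int,
    spacing: float = _SPACING,
    normal: tuple = (0.0, 0.0, 1.0),
    turns: float = 1.2,
    phase: float = 0.0,
    bow: float = 0.0,
) -> np.ndarray:
    """Positions of ``n_points`` linker CA atoms between two anchor points.

    The path is a chord-aligned coil whose radius is solved so the total arc
    length equals ``(n_points + 1) * spacing``, giving uniform consecutive-CA
    distances and absorbing arbitrary excess chain length compactly.
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    if n_points == 0:
        return np.empty((0, 3))
    chord = p1 - p0
    c = np.linalg.norm(chord)
    target = (n_points + 1) * spacing
    t_dense = np.linspace(0.0, 1.0, 1200)

    ch = chord / c
    nrm = np.asarray(normal, float)
    u = nrm - np.dot(nrm, ch) * ch
    if np.linalg.norm(u) < 1e-8:
        u = np.array([1.0, 0.0, 0.0]) - ch[0] * ch
    u /= np.linalg.norm(u)
    v = np.cross(ch, u)

    def curve(radius: float, n_turns: float) -> np.ndarray:
        env = np.sin(np.pi * t_dense)
        ang = 2.0 * np.pi * n_turns * t_dense + phase
        return (
            p0[None, :]
            + t_dense[:, None] * chord[None, :]
            + (radius * env * np.cos(ang))[:, None] * u[None, :]
            + (radius * env * np.sin(ang))[:, None] * v[None, :]
            + (bow * env)[:, None] * u[None, :]
        )

    def length(radius: float, n_turns: float) -> float:
        pts = curve(radius, n_turns)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def sample(pts: np.ndarray) -> np.ndarray:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s_targets = np.arange(1, n_points + 1) * cum[-1] / (n_points + 1)
        out = np.empty((n_points, 3))
        for d in range(3):
            out[:, d] = np.interp(s_targets, cum, pts[:, d])
        return out

    if length(0.0, turns) >= target:
        return sample(curve(0.0, turns))  # chord longer than chain: stretched
    # unwind the coil until the arc-length spacing also holds as straight-line
    # spacing (tight curvature would otherwise bunch consecutive residues)
    n_turns = turns
    for _ in range(8):
        radius = brentq(lambda r: length(r, n_turns) - target, 0.0, 80.0, xtol=1e-6)
        out = sample(curve(radius, n_turns))
        gaps = np.linalg.norm(np.diff(np.vstack([p0, out, p1]), axis=0), axis=1)
        if gaps.min() >= 0.8 * spacing:
            break
        n_turns *= 0.7
    return out


def _hinge_transform(theta: float, phi: float, psi: float) -> Rotation:
    return (
        Rotation.from_rotvec(psi * np.array([0.0, 0.0, 1.0]))
        * Rotation.from_rotvec(phi * np.array([0.0, 1.0, 0.0]))
        * Rotation.from_rotvec(theta * np.array([1.0, 0.0, 0.0]))
    )


def _assemble_backbone(layout: dict, angles: tuple[float, float, float]) -> np.ndarray:
    """CA/N/C/O backbone array (n_res, 4, 3) ordered (N, CA, C, O) for the
    flap orientation given by (theta, phi, psi)."""
    helices = layout["helices"]
    (h1a, h1b), (h2a, h2b), (h3a, h3b), (h4a, h4b) = helices
    n_res = len(layout["sequence"])

    fits = {}
    for name, (a, b) in zip(("H1", "H2", "H3", "H4"), helices):
        start, direction = _ANCHOR[name]
        fits[name] = _fit_helix(b - a + 1, (start, direction))

    # flap B (helices 2 and 3 plus the loop between) in the folded local pose
    rot = _hinge_transform(*angles)
    flap = lambda x: rot.apply(x - _HINGE_POINT) + _HINGE_POINT  # noqa: E731

    ca = np.full((n_res, 3), np.nan)

    def put_helix(name: str, a: int, b: int, transform=None) -> dict:
        atoms = fits[name]
        if transform is not None:
            atoms = {k: transform(v) for k, v in atoms.items()}
        ca[a - 1 : b] = atoms["CA"]
        return atoms

    helix_atoms = {}
    helix_atoms["H1"] = put_helix("H1", h1a, h1b)
    helix_atoms["H4"] = put_helix("H4", h4a, h4b)

    # flap B internals built locally, then rotated as a rigid unit
    h2_local = fits["H2"]
    h3_local = fits["H3"]
    n_l2 = h3a - h2b - 1
    if layout["cys_pairs"] and n_l2 == 12:
        # omega loop 34-45 routed below helix 3 through explicit waypoints so
        # that residue 35 ends adjacent to the helix-3 start (disulfide 35-46)
        # while the loop body keeps clear of the helix surface
        c46 = h3_local["CA"][0]
        wp = {
            0: c46 + np.array([-4.5, -1.5, 2.2]),  # residue 36
            3: c46 + np.array([-7.0, -7.0, 3.0]),  # residue 39
            5: c46 + np.array([-1.5, -10.0, 3.8]),  # residue 41
            7: c46 + np.array([3.5, -7.0, 3.2]),  # residue 43
            9: c46 + np.array([2.4, -2.2, 1.4]),  # residue 45
        }
        pre = _coil_path(
            h2_local["CA"][-1], wp[0], 2, normal=(-0.8, -1.0, 0.4), turns=0.6
        )
        pieces = [pre, wp[0][None, :]]
        keys = sorted(wp)
        for a, b in zip(keys, keys[1:]):
            between = _coil_path(wp[a], wp[b], b - a - 1, normal=(0.0, -0.6, 1.0), turns=0.6)
            pieces.extend([between, wp[b][None, :]])
        l2_local = np.vstack(pieces)
    elif n_l2 > 0:
        l2_local = _coil_path(
            h2_local["CA"][-1], h3_local["CA"][0], n_l2, normal=(-1.0, -0.5, 0.8)
        )
    else:
        l2_local = np.empty((0, 3))
    helix_atoms["H2"] = put_helix("H2", h2a, h2b, transform=flap)
    helix_atoms["H3"] = put_helix("H3", h3a, h3b, transform=flap)
    if n_l2 > 0:
        ca[h2b : h3a - 1] = flap(l2_local)

    # N-terminal tail into helix 1
    n_l0 = h1a - 1
    if n_l0 > 0:
        dir0 = np.asarray(_NTERM_DIR, dtype=float)
        dir0 /= np.linalg.norm(dir0)
        s0 = ca[h1a - 1] + 0.55 * (n_l0 + 1) * _SPACING * dir0
        ca[0:n_l0] = _coil_path(s0, ca[h1a - 1], n_l0, normal=_NTERM_NORMAL, turns=1.3)

    # cross-hinge linkers follow the current flap pose; the helix-1 to
    # helix-2 linker is routed over the hinge via a flap-relative waypoint so
    # it approaches the helix-2 start from the hinge side, not through it
    n_l1 = h2a - h1b - 1
    if n_l1 > 0:
        ca[h1b : h2a - 1] = _coil_path(
            ca[h1b - 1],
            ca[h2a - 1],
            n_l1,
            normal=_L1_NORMAL,
            turns=_L1_TURNS,
            bow=_L1_BOW,
        )
    n_l3 = h4a - h3b - 1
    if n_l3 > 0:
        ca[h3b : h4a - 1] = _coil_path(
            ca[h3b - 1],
            ca[h4a - 1],
            n_l3,
            normal=_L3_NORMAL,
            turns=_L3_TURNS,
            bow=_L3_BOW,
        )

    # C-terminal tail, routed so residue 77 ends near residue 8 (disulfide stem)
    n_l4 = n_res - h4b
    if n_l4 > 0:
        if layout["cys_pairs"] and n_l4 >= 5:
            target_res = DISULFIDE_PAIRS[0][0]  # residue 8
            u = np.asarray(_TAIL_APPROACH, dtype=float)
            u /= np.linalg.norm(u)
            e77 = ca[target_res - 1] + 5.5 * u
            ca[h4b : h4b + 4] = _coil_path(
                ca[h4b - 1], e77, 4, normal=(0.8, -0.4, -0.6), turns=0.8, phase=3.14159
            )
            ca[h4b + 4] = e77
            w = e77 - ca[h4b + 3]
            w /= np.linalg.norm(w)
            bend = np.asarray(_TAIL_BEND, dtype=float)
            w2 = w + bend
            w2 /= np.linalg.norm(w2)
            ca[h4b + 5] = e77 + _SPACING * w2
            w3 = w2 + bend
            w3 /= np.linalg.norm(w3)
            ca[h4b + 6] = ca[h4b + 5] + _SPACING * w3
        else:
            dir4 = np.array([0.3, -1.0, -0.3])
            dir4 /= np.linalg.norm(dir4)
            e4 = ca[h4b - 1] + 0.55 * (n_l4 + 1) * _SPACING * dir4
            tail = _coil_path(ca[h4b - 1], e4, n_l4, normal=(0.5, 0.0, -1.0), turns=1.1)
            ca[h4b:n_res] = tail

    # assemble full backbone: helix residues carry their NeRF atoms, linker
    # residues get N/C/O placed from the local chain direction with peptide
    # C-N continuity enforced at every junction
    bb = np.full((n_res, 4, 3), np.nan)
    is_helix = np.zeros(n_res, dtype=bool)
    for (a, b), name in zip(helices, ("H1", "H2", "H3", "H4")):
        atoms = helix_atoms[name]
        for k, key in enumerate(("N", "CA", "C", "O")):
            bb[a - 1 : b, k] = atoms[key]
        is_helix[a - 1 : b] = True

    def perp(vec: np.ndarray) -> np.ndarray:
        ref = np.array([0.3, 0.1, 0.9])
        out = np.cross(vec, ref)
        if np.linalg.norm(out) < 1e-6:
            out = np.cross(vec, np.array([1.0, 0.0, 0.0]))
        return out / np.linalg.norm(out)

    for i in range(n_res):
        if is_helix[i]:
            continue
        bb[i, 1] = ca[i]
    for i in range(n_res):
        if is_helix[i]:
            continue
        # amide N
        if i == 0:
            bb[i, 0] = ca[i] - 0.35 * (ca[i + 1] - ca[i])
        elif is_helix[i - 1]:
            c_prev = bb[i - 1, 2]
            d = ca[i] - c_prev
            bb[i, 0] = c_prev + 1.33 * d / np.linalg.norm(d)
        else:
            bb[i, 0] = ca[i] - 0.35 * (ca[i] - ca[i - 1])
        # carbonyl C
        if i == n_res - 1:
            bb[i, 2] = ca[i] + 0.45 * (ca[i] - ca[i - 1])
        elif is_helix[i + 1]:
            n_next = bb[i + 1, 0]
            d = ca[i] - n_next
            bb[i, 2] = n_next + 1.33 * d / np.linalg.norm(d)
        else:
            bb[i, 2] = ca[i] + 0.45 * (ca[i + 1] - ca[i])
        # carbonyl O perpendicular to the local chain direction
        lo = max(0, i - 1)
        hi = min(n_res - 1, i + 1)
        tangent = ca[hi] - ca[lo]
        bb[i, 3] = bb[i, 2] + 1.23 * perp(tangent)
    return bb


def _residue_com(bb: np.ndarray, residue: int) -> np.ndarray:
    masses = np.array([14.007, 12.011, 12.011, 15.999])
    x = bb[residue - 1]
    return (masses[:, None] * x).sum(axis=0) / masses.sum()


def _measure(bb: np.ndarray, diag: tuple) -> tuple[float, float]:
    y7, v34, i45, v70 = diag
    d1 = float(np.linalg.norm(_residue_com(bb, y7) - _residue_com(bb, v34)))
    d2 = float(np.linalg.norm(_residue_com(bb, i45) - _residue_com(bb, v70)))
    return d1, d2


# geometry solutions are deterministic per (size, targets); cache them so that
# repeated trajectory generation does not re-run the optimiser
_ANGLE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _solve_flap_angles(layout: dict, target: tuple[float, float], x0: np.ndarray) -> np.ndarray:
    def residuals(x):
        d1, d2 = _measure(_assemble_backbone(layout, tuple(x)), layout["diag"])
        return [d1 - target[0], d2 - target[1], 0.05 * x[1], 0.05 * x[2]]

    sol = least_squares(
        residuals,
        x0,
        bounds=([-2.8, -1.3, -1.3], [0.8, 1.3, 1.3]),
        xtol=1e-10,
        ftol=1e-12,
    )
    d1, d2 = _measure(_assemble_backbone(layout, tuple(sol.x)), layout["diag"])
    if abs(d1 - target[0]) > 0.5 or abs(d2 - target[1]) > 0.5:
        raise ValueError(
            f"target geometry (d1={target[0]}, d2={target[1]}) is unreachable: "
            f"best achievable ({d1:.2f}, {d2:.2f})"
        )
    return sol.x


def _add_cysteine_sites(bb: np.ndarray, layout: dict) -> dict[int, np.ndarray]:
    """SG pseudo-atom positions: paired cysteines bridge at 2.05 A on the
    CA-CA segment; the free cysteine points outward."""
    sites: dict[int, np.ndarray] = {}
    for a, b in layout["cys_pairs"]:
        ca_a, ca_b = bb[a - 1, 1], bb[b - 1, 1]
        mid = 0.5 * (ca_a + ca_b)
        u = ca_b - ca_a
        u /= np.linalg.norm(u)
        sites[a] = mid - 1.025 * u
        sites[b] = mid + 1.025 * u
    free = layout["free_cys"]
    if free is not None:
        # place the unpaired SG in the direction with the most clearance
        ca_free = bb[free - 1, 1]
        others = np.vstack([bb.reshape(-1, 3)] + [s[None, :] for s in sites.values()])
        others = others[np.linalg.norm(others - ca_free, axis=1) > 1e-9]
        best, best_d = None, -1.0
        for cand in _CANDIDATE_DIRECTIONS:
            pos = ca_free + 2.0 * cand
            d = float(np.linalg.norm(others - pos, axis=1).min())
            if d > best_d:
                best, best_d = pos, d
        sites[free] = best
    return sites


def _make_topology(layout: dict) -> Topology:
    sequence = layout["sequence"]
    cys_with_sg = {r for pair in layout["cys_pairs"] for r in pair}
    if layout["free_cys"] is not None:
        cys_with_sg.add(layout["free_cys"])
    residues = []
    atoms = []
    for i, letter in enumerate(sequence, start=1):
        resname = _ONE_TO_THREE.get(letter, "ALA")
        residues.append((i, resname))
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(name, element, atomic_mass(element), i, resname))
        if i in cys_with_sg:
            atoms.append(Atom("SG", "S", atomic_mass("S"), i, resname))
    return Topology(residues=residues, atoms=atoms)


def _frame_from_backbone(bb: np.ndarray, layout: dict, topology: Topology) -> Frame:
    sg = _add_cysteine_sites(bb, layout)
    coords = []
    for atom_index, atom in enumerate(topology.atoms):
        i = atom.residue_index
        if atom.name == "SG":
            coords.append(sg[i])
        else:
            k = {"N": 0, "CA": 1, "C": 2, "O": 3}[atom.name]
            coords.append(bb[i - 1, k])
    return Frame(np.array(coords))


def build_hinge_protein(
    params: HingeModelParams | None = None,
) -> tuple[Topology, Frame, Frame]:
    """Construct the hinge-protein topology plus its closed and open
    reference frames, with measured (d1, d2) within 0.5 A of the targets."""
    params = params or HingeModelParams()
    layout = _scaled_layout(params.n_residues)
    key = (params.n_residues, tuple(params.closed_geometry), tuple(params.open_geometry))
    if key in _ANGLE_CACHE:
        x_closed, x_open = _ANGLE_CACHE[key]
    else:
        x_closed = _solve_flap_angles(layout, params.closed_geometry, np.array([-0.25, 0.0, 0.0]))
        x_open = _solve_flap_angles(layout, params.open_geometry, np.array([-1.1, 0.0, 0.0]))
        _ANGLE_CACHE[key] = (x_closed, x_open)
    topology = _make_topology(layout)
    closed = _frame_from_backbone(_assemble_backbone(layout, tuple(x_closed)), layout, topology)
    open_ = _frame_from_backbone(_assemble_backbone(layout, tuple(x_open)), layout, topology)
    return topology, closed, open_


def spb_standin_models() -> tuple[Topology, Frame, Frame]:
    """Synthetic stand-in for the mature SP-B open/closed starting models.

    Built entirely from the published sequence facts and printed starting
    separations; it is a geometric surrogate, not an experimental structure.
    """
    return build_hinge_protein(HingeModelParams())


def simulate_hinge_trajectory(
    params: HingeModelParams | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Two-state Markov-switching trajectory with Gaussian positional noise."""
    params = params or HingeModelParams()
    topology, closed, open_ = build_hinge_protein(params)
    refs = {"closed": closed.coordinates, "open": open_.coordinates}
    rng = np.random.default_rng(params.seed)

    states = np.empty(params.n_frames, dtype="<U6")
    state = params.start_state
    switch = {"open": params.rate_open_to_closed, "closed": params.rate_closed_to_open}
    flip = {"open": "closed", "closed": "open"}
    for t in range(params.n_frames):
        states[t] = state
        if rng.random() < switch[state]:
            state = flip[state]

    frames = []
    for t in range(params.n_frames):
        noise = rng.normal(0.0, params.noise_sigma, size=refs[states[t]].shape)
        frames.append(Frame(refs[states[t]] + noise))
    trajectory = Trajectory(topology=topology, frames=frames, timestep=params.timestep)

    r_oc, r_co = params.rate_open_to_closed, params.rate_closed_to_open
    if r_oc + r_co > 0:
        pi_open = r_co / (r_co + r_oc)
    else:
        pi_open = 1.0 if params.start_state == "open" else 0.0
    truth = GroundTruth(
        state_sequence=states,
        stationary_occupancy=(pi_open, 1.0 - pi_open),
        reference_geometries={"closed": closed, "open": open_},
    )
    return trajectory, truth


def add_uniform_solvent(
    frame: Frame,
    topology: Topology,
    box_edge: float,
    n_solvent: int,
    exclusion_radius: float = 2.5,
    solvent_kind: str = "water",
    seed: int = 0,
    max_batches: int = 200,
) -> tuple[Topology, Frame]:
    """Surround the protein with single-site solvent of uniform bulk density.

    Sites are sampled uniformly in a cubic periodic box of edge ``box_edge``
    centered on the protein, rejecting positions within ``exclusion_radius``
    of any protein atom. Returns a new topology and frame carrying the box.
    """
    if solvent_kind == "water":
        resname, site, element = "WAT", "O", "O"
    elif solvent_kind == "chloroform":
        resname, site, element = "CL3", "C", "C"
    else:
        raise ValueError("solvent_kind must be 'water' or 'chloroform'")
    if n_solvent == 0:
        return topology, frame
    rng = np.random.default_rng(seed)
    center = frame.coordinates.mean(axis=0)
    tree = cKDTree(frame.coordinates)
    placed: list[np.ndarray] = []
    for _ in range(max_batches):
        need = n_solvent - len(placed)
        if need <= 0:
            break
        cand = center + (rng.random((2 * need + 16, 3)) - 0.5) * box_edge
        if exclusion_radius > 0:
            d, _ = tree.query(cand)
            cand = cand[d >= exclusion_radius]
        placed.extend(cand[:need])
    if len(placed) < n_solvent:
        raise ValueError(
            f"could not place {n_solvent} solvent sites outside "
            f"{exclusion_radius} A of the protein in a {box_edge} A box"
        )
    start = max(i for i, _ in topology.residues) + 1
    residues = list(topology.residues)
    atoms = list(topology.atoms)
    for k in range(n_solvent):
        residues.append((start + k, resname))
        atoms.append(Atom(site, element, atomic_mass(element), start + k, resname))
    new_top = Topology(residues=residues, atoms=atoms, chain_id=topology.chain_id)
    coords = np.vstack([frame.coordinates, np.array(placed)])
    return new_top, Frame(coords, box=np.full(3, float(box_edge)))
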