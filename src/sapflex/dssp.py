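"""Secondary-structure assignment by the Kabsch-Sander (DSSP) method.

Backbone hydrogen bonds are detected with the electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

(a bond exists when E < -0.5 kcal/mol), amide hydrogens are reconstructed at
1.01 A from N along the preceding C=O direction when absent from the file,
and the classic pattern rules turn the bond set into the 8-state alphabet
{H, G, I, E, B, T, S, -} with the standard priority (alpha helix over strand
over 3-10 over pi over turn over bend). The per-frame classes are binarized
into helical = {H, G, I} for the replicate-averaged occupancy maps.

The implementation follows the original DSSP program's conventions (energy
floor at -9.9 kcal/mol, overlap clamp below 0.5 A, proline as a non-donor,
two best acceptors per donor, 9 A CA pre-filter) so that it can be validated
against independent ports of that program.
"""

from __future__ import annotations

import warnings

import numpy as np

from .structure import Frame, Topology, Trajectory

__all__ = [
    "backbone_hbond_energy",
    "assign_secstruct",
    "assign_secstruct_trajectory",
    "helical_mask",
    "helicity_occupancy",
    "HBOND_CUTOFF",
    "HELICAL_CLASSES",
]

#: Hydrogen-bond acceptance threshold (kcal/mol).
HBOND_CUTOFF = -0.5
#: Classes counted as helical in the binarized occupancy maps.
HELICAL_CLASSES = frozenset({"H", "G", "I"})

_Q1Q2_F = 0.084 * 332.0  # coupling constant, kcal/mol * A
_E_MIN = -9.9  # energy floor of the original program
_MIN_DIST = 0.5  # overlap clamp distance (A)
_CA_PREFILTER = 9.0  # CA-CA distance beyond which E is taken as 0
_BREAK_CN = 2.5  # C(i)-N(i+1) distance defining a chain break
_BREAK_CACA = 4.5  # CA-CA distance defining a chain break
_H_BOND_LENGTH = 1.01  # reconstructed N-H length (A)


def backbone_hbond_energy(
    donor_n: np.ndarray,
    donor_h: np.ndarray,
    acceptor_c: np.ndarray,
    acceptor_o: np.ndarray,
) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy (kcal/mol).

    Overlapping geometries (any of the four distances below 0.5 A) are
    clamped to the -9.9 kcal/mol floor and flagged with a warning.
    """
    r_on = float(np.linalg.norm(acceptor_o - donor_n))
    r_ch = float(np.linalg.norm(acceptor_c - donor_h))
    r_oh = float(np.linalg.norm(acceptor_o - donor_h))
    r_cn = float(np.linalg.norm(acceptor_c - donor_n))
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        warnings.warn("overlapping donor/acceptor atoms; hydrogen-bond energy clamped")
        return _E_MIN
    energy = _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(energy, _E_MIN)


class _Backbone:
    """Backbone coordinate bookkeeping for one frame."""

    def __init__(self, frame: Frame, topology: Topology):
        residues = topology.protein_residues()
        self.n = len(residues)
        self.residue_ids = np.array([i for i, _ in residues])
        self.residue_names = [name.upper() for _, name in residues]
        self.N = np.full((self.n, 3), np.nan)
        self.CA = np.full((self.n, 3), np.nan)
        self.C = np.full((self.n, 3), np.nan)
        self.O = np.full((self.n, 3), np.nan)
        pos = {rid: k for k, rid in enumerate(self.residue_ids)}
        for i, atom in enumerate(topology.atoms):
            k = pos.get(atom.residue_index)
            if k is None:
                continue
            if atom.name == "N":
                self.N[k] = frame.coordinates[i]
            elif atom.name == "CA":
                self.CA[k] = frame.coordinates[i]
            elif atom.name == "C":
                self.C[k] = frame.coordinates[i]
            elif atom.name == "O":
                self.O[k] = frame.coordinates[i]
        self.valid = ~(
            np.isnan(self.N).any(1)
            | np.isnan(self.CA).any(1)
            | np.isnan(self.C).any(1)
            | np.isnan(self.O).any(1)
        )
        self.segment = self._segments()
        self.H = self._reconstruct_h()

    def _segments(self) -> np.ndarray:
        """Chain-segment id per residue; a new segment starts after a break."""
        seg = np.zeros(self.n, dtype=int)
        current = 0
        for i in range(1, self.n):
            broken = (
                not self.valid[i]
                or not self.valid[i - 1]
                or np.linalg.norm(self.N[i] - self.C[i - 1]) > _BREAK_CN
                or np.linalg.norm(self.CA[i] - self.CA[i - 1]) > _BREAK_CACA
            )
            if broken:
                current += 1
            seg[i] = current
        return seg

    def _reconstruct_h(self) -> np.ndarray:
        """Amide H at 1.01 A from N along the preceding C=O direction; NaN for
        prolines, segment-initial residues and invalid geometry."""
        H = np.full((self.n, 3), np.nan)
        for i in range(self.n):
            if not self.valid[i] or self.residue_names[i] == "PRO":
                continue
            if i == 0 or self.segment[i] != self.segment[i - 1] or not self.valid[i - 1]:
                continue
            co = self.C[i - 1] - self.O[i - 1]
            norm = np.linalg.norm(co)
            if norm < 1e-9:
                continue
            H[i] = self.N[i] + _H_BOND_LENGTH * co / norm
        return H

    def no_break(self, i: int, j: int) -> bool:
        lo, hi = min(i, j), max(i, j)
        return bool(np.all(self.segment[lo : hi + 1] == self.segment[lo]))


def _hbond_table(bb: _Backbone) -> tuple[np.ndarray, np.ndarray]:
    """Per-donor best-two acceptor table.

    Returns ``(acceptors, energies)`` of shape (n, 2); acceptor index -1
    means no partner. Donor d -> acceptor a is skipped when d == a + 1 (the
    peptide bond itself) and pre-filtered at 9 A CA separation.
    """
    n = bb.n
    can_donate = bb.valid & ~np.isnan(bb.H).any(1)

    def pdist(x, y):
        return np.linalg.norm(x[:, None, :] - y[None, :, :], axis=-1)

    with np.errstate(invalid="ignore"):
        ca = pdist(bb.CA, bb.CA)
        r_on = pdist(bb.N, bb.O)  # [donor, acceptor]
        r_ch = pdist(bb.H, bb.C)
        r_oh = pdist(bb.H, bb.O)
        r_cn = pdist(bb.N, bb.C)
        overlap = (
            np.fmin(np.fmin(r_on, r_ch), np.fmin(r_oh, r_cn)) < _MIN_DIST
        )
        E = _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    E = np.where(overlap, _E_MIN, E)
    E = np.fmax(E, _E_MIN)

    d_idx, a_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    invalid = (
        ~can_donate[:, None]
        | ~bb.valid[None, :]
        | (d_idx == a_idx)
        | (d_idx == a_idx + 1)  # the peptide bond itself
        | ~np.isfinite(ca)
        | (ca > _CA_PREFILTER)
        | ~np.isfinite(E)
    )
    E = np.where(invalid, 1e6, E)

    order = np.argsort(E, axis=1, kind="stable")[:, :2]
    acceptors = np.where(
        np.take_along_axis(E, order, axis=1) < 1e6, order, -1
    )
    energies = np.take_along_axis(E, order, axis=1)
    return acceptors, energies


def _bond_matrix(bb: _Backbone, acceptors: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """B[d, a] is True when donor d's NH bonds to acceptor a's CO."""
    n = bb.n
    B = np.zeros((n, n), dtype=bool)
    for slot in (0, 1):
        ok = (acceptors[:, slot] >= 0) & (energies[:, slot] < HBOND_CUTOFF)
        B[np.flatnonzero(ok), acceptors[ok, slot]] = True
    return B


def _find_bridges(bb: _Backbone, B: np.ndarray) -> list[tuple[str, int, int]]:
    """All (type, i, j) bridges with i + 2 < j, type in {'par', 'anti'}."""
    n = bb.n
    if n < 5:
        return []
    # interior residues whose i-1..i+1 stretch is unbroken
    interior = np.zeros(n, dtype=bool)
    interior[1 : n - 1] = bb.segment[: n - 2] == bb.segment[2:]
    interior &= bb.valid

    def b(di, ai):
        """B[i+di, j+ai] on the full (i, j) grid, False out of range."""
        out = np.zeros((n, n), dtype=bool)
        rows = np.arange(max(0, -di), min(n, n - di))
        cols = np.arange(max(0, -ai), min(n, n - ai))
        out[np.ix_(rows, cols)] = B[np.ix_(rows + di, cols + ai)]
        return out

    # parallel:     B[i+1, j] & B[j, i-1]  or  B[i, j-1] & B[j+1, i]
    # antiparallel: B[i, j] & B[j, i]      or  B[i+1, j-1] & B[j+1, i-1]
    par = (b(+1, 0) & b(0, -1).T) | (b(0, -1) & b(+1, 0).T)
    anti = (B & B.T) | (b(+1, -1) & b(+1, -1).T)
    mask = interior[:, None] & interior[None, :]
    iu = np.triu(np.ones((n, n), dtype=bool), k=3)
    bridges = [("par", int(i), int(j)) for i, j in zip(*np.nonzero(par & mask & iu))]
    anti_only = anti & ~par
    bridges += [("anti", int(i), int(j)) for i, j in zip(*np.nonzero(anti_only & mask & iu))]
    bridges.sort(key=lambda t: (t[1], t[2]))
    return bridges


def _ladders(bridges: list[tuple[str, int, int]]) -> list[dict]:
    """Group bridges into ladders, then bulge-link ladders of the same type
    (gap of at most one extra residue on one strand and four on the other)."""
    ladders: list[dict] = []
    for btype, i, j in bridges:
        placed = False
        for lad in ladders:
            if lad["type"] != btype:
                continue
            if i == lad["i"][-1] + 1:
                expected_j = lad["j"][-1] + 1 if btype == "par" else lad["j"][-1] - 1
                if j == expected_j:
                    lad["i"].append(i)
                    lad["j"].append(j)
                    placed = True
                    break
        if not placed:
            ladders.append({"type": btype, "i": [i], "j": [j]})

    merged = [dict(lad, group=g) for g, lad in enumerate(ladders)]
    for a in merged:
        for b in merged:
            if a is b or a["type"] != b["type"] or a["group"] == b["group"]:
                continue
            gap_i = b["i"][0] - a["i"][-1] - 1
            if a["type"] == "par":
                gap_j = b["j"][0] - a["j"][-1] - 1
            else:
                gap_j = a["j"][-1] - b["j"][0] - 1
            if gap_i < 0 or gap_j < 0:
                continue
            if (gap_i <= 1 and gap_j <= 4) or (gap_i <= 4 and gap_j <= 1):
                g = min(a["group"], b["group"])
                old = max(a["group"], b["group"])
                for lad in merged:
                    if lad["group"] == old:
                        lad["group"] = g
    return merged


def assign_secstruct(frame: Frame, topology: Topology) -> np.ndarray:
    """Per-residue DSSP class labels for one frame.

    Returns an array of single-character labels over the protein residues of
    the topology, '-' for loop/irregular.
    """
    bb = _Backbone(frame, topology)
    n = bb.n
    ss = np.array(["-"] * n, dtype="<U1")
    if n < 5 or not bb.valid.any():
        return ss
    acceptors, energies = _hbond_table(bb)
    B = _bond_matrix(bb, acceptors, energies)

    # n-turn start flags: CO(i) accepts NH(i+stride)
    start = {s: np.zeros(n, dtype=bool) for s in (3, 4, 5)}
    for stride in (3, 4, 5):
        idx = np.arange(n - stride)
        start[stride][idx] = (bb.segment[idx] == bb.segment[idx + stride]) & B[
            idx + stride, idx
        ]

    # beta bridges and ladders (before helices: alpha overrides strand)
    bridges = _find_bridges(bb, B)
    ladders = _ladders(bridges)
    groups: dict[int, list[dict]] = {}
    for lad in ladders:
        groups.setdefault(lad["group"], []).append(lad)
    for members in groups.values():
        n_bridges = sum(len(lad["i"]) for lad in members)
        extended = n_bridges > 1
        code = "E" if extended else "B"
        lo_i = min(lad["i"][0] for lad in members)
        hi_i = max(lad["i"][-1] for lad in members)
        j_vals = [j for lad in members for j in lad["j"]]
        lo_j, hi_j = min(j_vals), max(j_vals)
        if extended:
            ss[lo_i : hi_i + 1] = code
            ss[lo_j : hi_j + 1] = code
        else:
            ss[lo_i] = code
            ss[lo_j] = code

    # alpha helix: 4-turn at i-1 and i => H for i..i+3 (overrides strand)
    for i in range(1, n - 3):
        if start[4][i] and start[4][i - 1]:
            ss[i : i + 4] = "H"

    # 3-10 helix: onto loop or existing G only
    for i in range(1, n - 2):
        if start[3][i] and start[3][i - 1]:
            if all(c in ("-", "G") for c in ss[i : i + 3]):
                ss[i : i + 3] = "G"

    # pi helix: lowest helix priority, onto loop or existing I only
    for i in range(1, n - 4):
        if start[5][i] and start[5][i - 1]:
            if all(c in ("-", "I") for c in ss[i : i + 5]):
                ss[i : i + 5] = "I"

    # hydrogen-bonded turn
    for i in range(n):
        if ss[i] != "-":
            continue
        is_turn = any(
            i - k >= 0 and start[stride][i - k]
            for stride in (3, 4, 5)
            for k in range(1, stride)
        )
        if is_turn:
            ss[i] = "T"

    # bend: CA-chain curvature above 70 degrees
    for i in range(2, n - 2):
        if ss[i] != "-" or not bb.no_break(i - 2, i + 2):
            continue
        u = bb.CA[i] - bb.CA[i - 2]
        v = bb.CA[i + 2] - bb.CA[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        kappa = np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)))
        if kappa > 70.0:
            ss[i] = "S"
    return ss


def assign_secstruct_trajectory(trajectory: Trajectory) -> np.ndarray:
    """(n_frames, n_residues) DSSP class labels."""
    return np.stack(
        [assign_secstruct(f, trajectory.topology) for f in trajectory.frames]
    )


def helical_mask(classes: np.ndarray) -> np.ndarray:
    """Binarize DSSP classes into helical (pi, alpha and 3-10) vs not."""
    return np.isin(classes, sorted(HELICAL_CLASSES))


def helicity_occupancy(maps: list[np.ndarray], time_bins: int = 100) -> np.ndarray:
    """Replicate-averaged helicity occupancy on a common fractional time axis.

    ``maps`` are per-replicate (n_frames, n_residues) boolean matrices with a
    shared residue dimension but possibly unequal frame counts; each
    replicate's frames are assigned to ``time_bins`` equal fraction-of-
    trajectory bins. Entry (b, r) is the fraction of (replicate, frame)
    samples in bin b for which residue r is helical; bins that receive no
    frames are NaN.
    """
    if not maps:
        raise ValueError("no replicate maps supplied")
    n_res = maps[0].shape[1]
    for m in maps:
        if m.ndim != 2 or m.shape[1] != n_res:
            raise ValueError("replicate maps must share the residue dimension")
    total = np.zeros((time_bins, n_res))
    count = np.zeros((time_bins, 1))
    for m in maps:
        n_frames = m.shape[0]
        bins = np.minimum((np.arange(n_frames) * time_bins) // n_frames, time_bins - 1)
        for b in range(time_bins):
            rows = m[bins == b]
            if rows.size:
                total[b] += rows.sum(axis=0)
                count[b] += rows.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        occupancy = np.where(count > 0, total / count, np.nan)
    return occupancy
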