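"""Backbone geometry construction from internal coordinates.

Chains are grown atom by atom with the standard NeRF (natural extension
reference frame) placement rule, using ideal peptide bond lengths and angles,
so that segments built with helical dihedrals (phi = -57, psi = -47) are
genuine alpha helices that hydrogen-bond correctly under the Kabsch-Sander
criterion.
"""

from __future__ import annotations

import numpy as np

__all__ = ["place_atom", "build_backbone", "ideal_alpha_helix"]

# ideal backbone internal coordinates (Angstrom / degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.6
_A_CA_C_O = 120.8


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float
) -> np.ndarray:
    """Position of atom D given A-B-C, |CD|, angle(B,C,D) and dihedral(A,B,C,D)
    (angles in degrees)."""
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: np.ndarray, psi: np.ndarray, omega: float = 180.0
) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O coordinates for a chain with the given per-residue
    dihedrals (degrees). ``phi[0]`` is unused (no preceding C)."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res or n_res < 1:
        raise ValueError("phi and psi must be equal-length, non-empty")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])
    for i in range(n_res):
        # carbonyl O trans to the next N (dihedral psi + 180 about N-CA-C)
        O[i] = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def ideal_alpha_helix(n_res: int) -> dict[str, np.ndarray]:
    """Backbone of an ideal alpha helix (phi = -57, psi = -47)."""
    if n_res < 2:
        raise ValueError("a helix needs at least 2 residues")
    phi = np.full(n_res, -57.0)
    psi = np.full(n_res, -47.0)
    return build_backbone(phi, psi)
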