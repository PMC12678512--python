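"""Independent oracles used by the test suite.

These deliberately share no code with the implementation paths they check:
the superposition oracle solves the optimal-rotation problem by the Horn
quaternion eigenvalue method instead of SVD, and the DSSP oracle is mdtraj's
port of the original assignment program.
"""

from __future__ import annotations

import tempfile

import numpy as np


def quaternion_rmsd(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Minimal weighted RMSD via the quaternion (Horn) eigenvalue method."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = mobile.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    x = mobile - w @ mobile
    y = reference - w @ reference
    S = (x * w[:, None]).T @ y
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = np.sum(w * (np.sum(x**2, axis=1) + np.sum(y**2, axis=1))) - 2.0 * lam
    return float(np.sqrt(max(msd, 0.0)))


def mdtraj_dssp(trajectory) -> np.ndarray:
    """Reference DSSP labels from mdtraj (loop mapped to '-')."""
    import mdtraj as md

    from sapflex.pdbio import write_pdb_models

    with tempfile.NamedTemporaryFile(suffix=".pdb") as fh:
        write_pdb_models(trajectory, fh.name)
        m = md.load_pdb(fh.name)
    ref = md.compute_dssp(m, simplified=False)
    return np.where(ref == " ", "-", ref)
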