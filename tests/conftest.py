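import numpy as np
import pytest

from sapflex.builder import ideal_alpha_helix
from sapflex.structure import Atom, Frame, Topology, Trajectory, atomic_mass
from sapflex.synthetic import (
    HingeModelParams,
    simulate_hinge_trajectory,
    spb_standin_models,
)


@pytest.fixture(scope="session")
def standin():
    """Synthetic stand-in for the SP-B starting models:
    (topology, closed frame, open frame)."""
    return spb_standin_models()


@pytest.fixture(scope="session")
def fast_switching():
    """600-frame two-state trajectory with rapid (0.5/0.5) switching, so the
    state sequence is nearly i.i.d. and binomial error bars apply."""
    params = HingeModelParams(
        n_frames=600, seed=11, rate_open_to_closed=0.5, rate_closed_to_open=0.5
    )
    return simulate_hinge_trajectory(params)


def make_backbone_topology(n_res: int, res_names=None) -> Topology:
    """Backbone-only (N, CA, C, O) topology of ALA residues by default."""
    residues, atoms = [], []
    for i in range(1, n_res + 1):
        name = res_names[i - 1] if res_names else "ALA"
        residues.append((i, name))
        for atom_name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(atom_name, element, atomic_mass(element), i, name))
    return Topology(residues=residues, atoms=atoms)


def helix_frame(n_res: int) -> tuple[Topology, Frame]:
    """Ideal poly-alanine alpha helix as (topology, frame)."""
    h = ideal_alpha_helix(n_res)
    coords = np.concatenate(
        [np.stack([h["N"][i], h["CA"][i], h["C"][i], h["O"][i]]) for i in range(n_res)]
    )
    return make_backbone_topology(n_res), Frame(coords)


@pytest.fixture(scope="session")
def ideal_helix_traj():
    top, frame = helix_frame(15)
    return Trajectory(top, [frame])
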