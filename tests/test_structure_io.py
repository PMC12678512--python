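import numpy as np
import pytest

from sapflex.pdbio import PDBParseError, read_coord_table, read_pdb_models, write_coord_table, write_pdb_models
from sapflex.sequence import (
    SPB_MATURE_SEQUENCE,
    count_charged_residues,
    extract_sequence,
    neutralizing_ion_count,
)
from sapflex.structure import (
    Atom,
    Frame,
    Topology,
    Trajectory,
    center_of_mass,
    detect_disulfides,
)

from conftest import make_backbone_topology

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
TER
END
"""

BROKEN_MULTIMODEL = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ENDMDL
END
"""


class TestReadPdb:
    def test_single_model(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        traj = read_pdb_models(path)
        assert traj.n_frames == 1
        assert traj.topology.n_atoms == 3
        assert traj.topology.atoms[1].name == "CA"
        assert traj.topology.atoms[1].element == "C"

    def test_inconsistent_model_named_in_error(self, tmp_path):
        path = tmp_path / "broken.pdb"
        path.write_text(BROKEN_MULTIMODEL)
        with pytest.raises(PDBParseError, match="model 2"):
            read_pdb_models(path)

    def test_standin_has_79_residues(self, standin, tmp_path):
        top, closed, _ = standin
        path = tmp_path / "standin.pdb"
        write_pdb_models(Trajectory(top, [closed]), path)
        reread = read_pdb_models(path)
        assert reread.topology.n_residues == 79

    def test_unknown_residue_warns_but_parses(self, tmp_path):
        path = tmp_path / "odd.pdb"
        path.write_text(MINIMAL_PDB.replace("ALA", "XYZ"))
        with pytest.warns(UserWarning, match="XYZ"):
            traj = read_pdb_models(path)
        assert traj.topology.n_atoms == 3

    def test_roundtrip_preserves_coordinates_and_topology(self, standin, tmp_path):
        top, closed, open_ = standin
        traj = Trajectory(top, [closed, open_], timestep=0.5)
        path = tmp_path / "rt.pdb"
        write_pdb_models(traj, path)
        back = read_pdb_models(path, timestep=0.5)
        assert back.n_frames == 2
        assert [a.name for a in back.topology.atoms] == [a.name for a in top.atoms]
        assert back.topology.residues == top.residues
        np.testing.assert_allclose(
            back.coords_array(), traj.coords_array(), atol=1.5e-3
        )

    def test_coord_table_roundtrip(self, standin, tmp_path):
        top, closed, open_ = standin
        traj = Trajectory(top, [closed, open_])
        path = tmp_path / "coords.dat"
        write_coord_table(traj, path)
        back = read_coord_table(path, top)
        np.testing.assert_allclose(back.coords_array(), traj.coords_array(), atol=1e-3)


class TestSequence:
    def test_extract_basic_and_nonstandard(self):
        top = make_backbone_topology(3, res_names=["ALA", "GLY", "XYZ"])
        assert extract_sequence(top) == "AGX"

    def test_standin_sequence_is_mature_spb(self, standin):
        top, _, _ = standin
        seq = extract_sequence(top)
        assert len(seq) == 79
        assert seq == SPB_MATURE_SEQUENCE
        assert seq.count("C") == 7

    def test_empty_topology_rejected(self):
        with pytest.raises(ValueError):
            extract_sequence(Topology(residues=[], atoms=[]))

    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("KRDE", (2, 2, 0)),
            ("GGGG", (0, 0, 0)),
            (SPB_MATURE_SEQUENCE, (9, 2, 7)),
            ("HHH", (0, 0, 0)),  # histidine neutral at pH 7.4
        ],
    )
    def test_charge_census(self, seq, expected):
        s = count_charged_residues(seq)
        assert (s.n_positive, s.n_negative, s.net_charge) == expected

    def test_census_is_order_invariant(self):
        rng = np.random.default_rng(0)
        seq = SPB_MATURE_SEQUENCE
        shuffled = "".join(rng.permutation(list(seq)))
        assert count_charged_residues(seq) == count_charged_residues(shuffled)

    def test_termini_cancel_for_free_peptide(self):
        with_term = count_charged_residues("KRDE", include_termini=True)
        without = count_charged_residues("KRDE", include_termini=False)
        assert with_term.net_charge == without.net_charge

    @pytest.mark.parametrize(
        "net, expected",
        [(7, ("anion", 7)), (0, ("none", 0)), (-3, ("cation", 3))],
    )
    def test_neutralizing_ions(self, net, expected):
        from sapflex.sequence import ChargeSummary

        assert neutralizing_ion_count(ChargeSummary(0, 0, net)) == expected


class TestDisulfides:
    def test_no_cysteines(self):
        top = make_backbone_topology(4)
        frame = Frame(np.random.default_rng(0).normal(size=(top.n_atoms, 3)))
        assert detect_disulfides(frame, top) == []

    def test_constructed_pair(self):
        residues = [(1, "CYS"), (2, "CYS")]
        atoms = [
            Atom("CA", "C", 12.011, 1, "CYS"),
            Atom("SG", "S", 32.06, 1, "CYS"),
            Atom("CA", "C", 12.011, 2, "CYS"),
            Atom("SG", "S", 32.06, 2, "CYS"),
        ]
        top = Topology(residues=residues, atoms=atoms)
        frame = Frame(
            np.array([[0, 0, 0], [1.8, 0, 0], [5.5, 0, 0], [3.85, 0, 0]], dtype=float)
        )
        assert detect_disulfides(frame, top) == [(1, 2)]

    def test_standin_closed_model_recovers_saposin_topology(self, standin):
        top, closed, _ = standin
        assert detect_disulfides(closed, top) == [(8, 77), (11, 71), (35, 46)]

    def test_missing_sg_warns(self):
        residues = [(1, "CYS")]
        atoms = [Atom("CA", "C", 12.011, 1, "CYS")]
        top = Topology(residues=residues, atoms=atoms)
        with pytest.warns(UserWarning, match="SG"):
            assert detect_disulfides(Frame(np.zeros((1, 3))), top) == []


class TestCenterOfMass:
    def test_single_atom(self):
        top = make_backbone_topology(1)
        coords = np.tile([1.0, 2.0, 3.0], (4, 1))
        np.testing.assert_allclose(center_of_mass(Frame(coords), top, (1, 1)), [1, 2, 3])

    def test_equal_masses_cancel(self):
        residues = [(1, "GLY")]
        atoms = [Atom("O1", "O", 15.999, 1, "GLY"), Atom("O2", "O", 15.999, 1, "GLY")]
        top = Topology(residues=residues, atoms=atoms)
        frame = Frame(np.array([[2.0, 0, 0], [-2.0, 0, 0]]))
        np.testing.assert_allclose(center_of_mass(frame, top, (1, 1)), [0, 0, 0], atol=1e-12)

    def test_mixed_mass_matches_hand_arithmetic(self):
        # H at x=0, C at x=1, N at x=2, O at x=3:
        # com_x = (1.008*0 + 12.011*1 + 14.007*2 + 15.999*3) / 43.025
        residues = [(1, "GLY")]
        names = [("H1", "H"), ("C1", "C"), ("N1", "N"), ("O1", "O")]
        masses = [1.008, 12.011, 14.007, 15.999]
        atoms = [Atom(n, e, m, 1, "GLY") for (n, e), m in zip(names, masses)]
        top = Topology(residues=residues, atoms=atoms)
        frame = Frame(np.array([[i, 0, 0] for i in range(4)], dtype=float))
        expected = (12.011 + 2 * 14.007 + 3 * 15.999) / sum(masses)
        np.testing.assert_allclose(center_of_mass(frame, top, (1, 1))[0], expected, rtol=1e-12)

    def test_empty_selection_rejected(self):
        top = make_backbone_topology(2)
        with pytest.raises(ValueError):
            center_of_mass(Frame(np.zeros((8, 3))), top, (5, 6))
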