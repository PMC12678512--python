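import numpy as np
import pytest
from scipy.stats import chisquare

from sapflex.conformation import classify_frame, conformation_series
from sapflex.landscape import bin_states, free_energy
from sapflex.structure import Trajectory
from sapflex.superpose import rmsf_per_residue
from sapflex.synthetic import (
    DISULFIDE_PAIRS,
    HingeModelParams,
    add_uniform_solvent,
    build_hinge_protein,
    simulate_hinge_trajectory,
)


class TestBuildHingeProtein:
    def test_default_geometries_match_targets(self, standin):
        top, closed, open_ = standin
        traj = Trajectory(top, [closed, open_])
        series = conformation_series(traj)
        assert series.d1[0] == pytest.approx(15.0, abs=0.5)
        assert series.d2[0] == pytest.approx(14.0, abs=0.5)
        assert series.d1[1] == pytest.approx(25.0, abs=0.5)
        assert series.d2[1] == pytest.approx(27.0, abs=0.5)

    def test_frames_classify_as_their_basin(self, standin):
        top, closed, open_ = standin
        series = conformation_series(Trajectory(top, [closed, open_]))
        assert classify_frame(series.d1[0], series.d2[0]) == "closed"
        assert classify_frame(series.d1[1], series.d2[1]) == "open"

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            HingeModelParams(n_residues=5)

    def test_chain_is_continuous(self, standin):
        top, closed, open_ = standin
        ca = {a.residue_index: i for i, a in enumerate(top.atoms) if a.name == "CA"}
        for frame in (closed, open_):
            x = frame.coordinates
            gaps = [
                np.linalg.norm(x[ca[i + 1]] - x[ca[i]]) for i in range(1, 79)
            ]
            assert max(gaps) < 4.5  # no chain break under the DSSP rule

    def test_invalid_geometry_targets_rejected(self):
        with pytest.raises(ValueError, match="closed band"):
            HingeModelParams(closed_geometry=(19.0, 14.0))
        with pytest.raises(ValueError, match="open band"):
            HingeModelParams(open_geometry=(18.0, 27.0))

    def test_cysteine_sites_only_pair_as_disulfides(self, standin):
        from sapflex.structure import detect_disulfides

        top, closed, open_ = standin
        for frame in (closed, open_):
            assert detect_disulfides(frame, top) == sorted(DISULFIDE_PAIRS)

    def test_smaller_protein_builds(self):
        params = HingeModelParams(
            n_residues=40, closed_geometry=(14.0, 14.0), open_geometry=(24.0, 24.0)
        )
        try:
            top, closed, open_ = build_hinge_protein(params)
        except ValueError as err:
            assert "unreachable" in str(err)
            return
        assert top.n_residues == 40


class TestSimulateTrajectory:
    def test_absorbing_rates_stay_in_start_state(self):
        params = HingeModelParams(
            n_frames=50, rate_open_to_closed=0.0, rate_closed_to_open=0.0, seed=1
        )
        _, truth = simulate_hinge_trajectory(params)
        assert set(truth.state_sequence) == {"closed"}
        assert truth.stationary_occupancy == (0.0, 1.0)

    def test_same_seed_is_bitwise_reproducible(self):
        params = HingeModelParams(n_frames=30, seed=77)
        t1, g1 = simulate_hinge_trajectory(params)
        t2, g2 = simulate_hinge_trajectory(params)
        np.testing.assert_array_equal(t1.coords_array(), t2.coords_array())
        np.testing.assert_array_equal(g1.state_sequence, g2.state_sequence)

    def test_symmetric_rates_occupancy_within_3se(self):
        params = HingeModelParams(
            n_frames=10_000, seed=3, rate_open_to_closed=0.5, rate_closed_to_open=0.5
        )
        _, truth = simulate_hinge_trajectory(params)
        frac_open = np.mean(truth.state_sequence == "open")
        se = np.sqrt(0.25 / params.n_frames)
        assert abs(frac_open - 0.5) < 3 * se

    def test_stationary_law_from_asymmetric_rates(self):
        params = HingeModelParams(
            n_frames=10, rate_open_to_closed=0.3, rate_closed_to_open=0.1
        )
        _, truth = simulate_hinge_trajectory(params)
        assert truth.stationary_occupancy[0] == pytest.approx(0.25)
        assert sum(truth.stationary_occupancy) == pytest.approx(1.0)

    def test_landscape_recovers_stationary_occupancy(self, fast_switching):
        traj, truth = fast_switching
        series = conformation_series(traj)
        fel = free_energy(bin_states(series.d1, series.d2, 0.5))
        df = fel.to_dataframe()
        p_open = df.loc[df.d1_center >= 20.0, "P"].sum()
        pi = truth.stationary_occupancy[0]
        se = np.sqrt(pi * (1 - pi) / traj.n_frames)
        assert abs(p_open - pi) < 3 * se

    def test_rmsf_recovery_flat_sigma_sqrt3(self):
        sigma = 0.5
        params = HingeModelParams(
            n_frames=150, seed=8, noise_sigma=sigma,
            rate_open_to_closed=0.0, rate_closed_to_open=0.0,
        )
        traj, truth = simulate_hinge_trajectory(params)
        profile = rmsf_per_residue(
            traj, average=truth.reference_geometries["closed"], align=False
        )
        vals = profile.per_residue_rmsf
        se = np.nanstd(vals) / np.sqrt(np.sum(~np.isnan(vals)))
        assert abs(np.nanmean(vals) - sigma * np.sqrt(3)) < 3 * se


class TestUniformSolvent:
    def test_zero_solvent_is_identity(self, standin):
        top, closed, _ = standin
        new_top, new_frame = add_uniform_solvent(closed, top, 60.0, 0)
        assert new_top is top and new_frame is closed

    def test_placement_respects_exclusion_radius(self, standin):
        from scipy.spatial import cKDTree

        top, closed, _ = standin
        excl = 3.0
        new_top, frame = add_uniform_solvent(
            closed, top, 70.0, 500, exclusion_radius=excl, seed=4
        )
        protein = frame.coordinates[: top.n_atoms]
        solvent = frame.coordinates[top.n_atoms :]
        d, _ = cKDTree(protein).query(solvent)
        assert d.min() >= excl

    def test_octant_uniformity_chi_square(self):
        from sapflex.structure import Atom, Frame, Topology, atomic_mass

        top = Topology(
            residues=[(1, "GLY")], atoms=[Atom("CA", "C", atomic_mass("C"), 1, "GLY")]
        )
        frame = Frame(np.zeros((1, 3)))
        _, solvated = add_uniform_solvent(frame, top, 50.0, 4000, exclusion_radius=0.0, seed=2)
        sites = solvated.coordinates[1:]
        octant = (
            (sites[:, 0] > 0).astype(int)
            + 2 * (sites[:, 1] > 0).astype(int)
            + 4 * (sites[:, 2] > 0).astype(int)
        )
        counts = np.bincount(octant, minlength=8)
        assert chisquare(counts).pvalue > 0.01

    def test_impossible_placement_rejected(self, standin):
        top, closed, _ = standin
        with pytest.raises(ValueError, match="could not place"):
            add_uniform_solvent(closed, top, 20.0, 2000, exclusion_radius=30.0, seed=0)

    def test_solvent_kind_sets_residue_names(self, standin):
        top, closed, _ = standin
        wat_top, _ = add_uniform_solvent(closed, top, 60.0, 5, solvent_kind="water")
        cl3_top, _ = add_uniform_solvent(closed, top, 60.0, 5, solvent_kind="chloroform")
        assert wat_top.residues[-1][1] == "WAT"
        assert cl3_top.residues[-1][1] == "CL3"
        with pytest.raises(ValueError):
            add_uniform_solvent(closed, top, 60.0, 5, solvent_kind="benzene")
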