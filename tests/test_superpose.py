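import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sapflex.structure import Frame, Trajectory
from sapflex.superpose import (
    average_structure,
    find_flexible_regions,
    flexibility_profile,
    kabsch_superpose,
    rmsd_series,
    rmsf_per_residue,
)

from conftest import make_backbone_topology
from oracles import quaternion_rmsd


def random_instance(rng, n=10, weighted=True):
    mobile = rng.normal(scale=3.0, size=(n, 3))
    reference = rng.normal(scale=3.0, size=(n, 3))
    weights = rng.uniform(0.5, 16.0, size=n) if weighted else None
    return mobile, reference, weights


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        mobile = x @ R.T + np.array([3.0, -1.0, 7.0])
        res = kabsch_superpose(mobile, x)
        assert res.rmsd < 1e-6
        np.testing.assert_allclose(res.rotation @ R, np.eye(3), atol=1e-8)

    def test_rotation_is_proper_orthogonal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m, r, w = random_instance(rng)
            res = kabsch_superpose(m, r, w)
            np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_oracle(self):
        """SVD solution agrees with the Horn quaternion eigenvalue method."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            m, r, w = random_instance(rng, n=int(rng.integers(4, 20)))
            assert kabsch_superpose(m, r, w).rmsd == pytest.approx(
                quaternion_rmsd(m, r, w), abs=1e-8
            )

    def test_superposed_never_worse_than_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m, r, w = random_instance(rng)
            raw = np.sqrt(np.sum(w * np.sum((m - r) ** 2, axis=1)) / w.sum())
            assert kabsch_superpose(m, r, w).rmsd <= raw + 1e-12

    def test_invariant_to_rigid_motion_of_mobile(self):
        rng = np.random.default_rng(4)
        m, r, w = random_instance(rng)
        base = kabsch_superpose(m, r, w).rmsd
        R = Rotation.from_euler("zyx", [0.3, 1.2, -0.7]).as_matrix()
        moved = m @ R.T + np.array([-4.0, 2.0, 9.0])
        assert kabsch_superpose(moved, r, w).rmsd == pytest.approx(base, abs=1e-6)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_copies_of_reference_give_zero(self, standin):
        top, closed, _ = standin
        traj = Trajectory(top, [closed] * 3)
        np.testing.assert_allclose(rmsd_series(traj, closed), 0.0, atol=1e-10)

    def test_translation_removed(self, standin):
        top, closed, _ = standin
        shifted = Frame(closed.coordinates + np.array([5.0, 0.0, 0.0]))
        traj = Trajectory(top, [shifted])
        assert rmsd_series(traj, closed)[0] == pytest.approx(0.0, abs=1e-10)

    def test_series_is_composition_of_single_superpositions(self, fast_switching):
        traj, _ = fast_switching
        short = traj[:10]
        ref = traj.frames[0]
        series = rmsd_series(short, ref)
        sel = short.topology.select({"N", "CA", "C"}, protein_only=True)
        w = short.topology.masses[sel]
        expected = [
            kabsch_superpose(f.coordinates[sel], ref.coordinates[sel], w).rmsd
            for f in short.frames
        ]
        np.testing.assert_allclose(series, expected, atol=1e-12)

    def test_empty_selection_rejected(self, standin):
        top, closed, _ = standin
        with pytest.raises(ValueError):
            rmsd_series(Trajectory(top, [closed]), closed, selection={"ZZ"})


class TestAverageStructure:
    def test_single_frame_is_identity(self, standin):
        top, closed, _ = standin
        avg = average_structure(Trajectory(top, [closed]))
        np.testing.assert_allclose(avg.coordinates, closed.coordinates, atol=1e-9)

    def test_rotated_copies_average_to_zero_deviation(self, standin):
        top, closed, _ = standin
        R = Rotation.from_euler("xyz", [0.5, 0.2, -0.9]).as_matrix()
        rotated = Frame(closed.coordinates @ R.T + 4.0)
        traj = Trajectory(top, [closed, rotated])
        avg = average_structure(traj)
        assert rmsd_series(traj, avg).max() < 1e-6

    def test_noisy_average_near_generator_reference(self, standin):
        top, closed, _ = standin
        rng = np.random.default_rng(7)
        sigma, n = 0.3, 40
        frames = [Frame(closed.coordinates + rng.normal(0, sigma, closed.coordinates.shape)) for _ in range(n)]
        avg = average_structure(Trajectory(top, frames))
        res = kabsch_superpose(avg.coordinates, closed.coordinates)
        # mean of n noisy copies deviates by ~ sigma*sqrt(3)/sqrt(n) per atom
        assert res.rmsd < 5 * sigma * np.sqrt(3.0 / n)


class TestRmsf:
    def test_static_trajectory_zero(self, standin):
        top, closed, _ = standin
        profile = rmsf_per_residue(Trajectory(top, [closed] * 4))
        np.testing.assert_allclose(profile.per_residue_rmsf, 0.0, atol=1e-9)
        assert profile.peak_regions == []

    def test_isotropic_noise_gives_sigma_sqrt3_without_alignment(self, standin):
        """i.i.d. per-coordinate noise of width sigma has RMSF sigma*sqrt(3)."""
        top, closed, _ = standin
        rng = np.random.default_rng(5)
        sigma, n = 1.0, 200
        frames = [
            Frame(closed.coordinates + rng.normal(0, sigma, closed.coordinates.shape))
            for _ in range(n)
        ]
        profile = rmsf_per_residue(Trajectory(top, frames), average=closed, align=False)
        expected = sigma * np.sqrt(3)
        se = np.nanstd(profile.per_residue_rmsf) / np.sqrt(len(profile.per_residue_rmsf))
        assert abs(np.nanmean(profile.per_residue_rmsf) - expected) < 3 * se

    def test_threshold_is_mean_plus_sd(self):
        # two-point profile with mean 11.4 and sd 2.9 sets the peak cut at 14.3
        profile = flexibility_profile([1, 2], [8.5, 14.3])
        assert profile.mean == pytest.approx(11.4)
        assert profile.sd == pytest.approx(2.9)
        assert profile.threshold == pytest.approx(14.3)

    def test_rmsf_invariant_under_global_rigid_motion(self, fast_switching):
        traj, _ = fast_switching
        short = traj[:30]
        base = rmsf_per_residue(short).per_residue_rmsf
        R = Rotation.from_euler("zxy", [1.0, -0.4, 0.8]).as_matrix()
        moved = Trajectory(
            short.topology,
            [Frame(f.coordinates @ R.T + np.array([10.0, -3.0, 2.0])) for f in short.frames],
            short.timestep,
        )
        np.testing.assert_allclose(
            rmsf_per_residue(moved).per_residue_rmsf, base, atol=1e-6
        )


class TestFlexibleRegions:
    def test_flat_profile_has_no_peaks(self):
        profile = flexibility_profile(np.arange(1, 11), np.full(10, 2.0))
        assert find_flexible_regions(profile) == []

    def test_single_spike(self):
        rmsf = np.full(60, 1.0)
        rmsf[39] = 8.0  # residue 40
        profile = flexibility_profile(np.arange(1, 61), rmsf)
        assert find_flexible_regions(profile) == [(40, 40)]

    def test_two_constructed_runs(self):
        rmsf = np.full(30, 1.0)
        rmsf[0:5] = 9.0  # residues 1-5
        rmsf[22:25] = 9.0  # residues 23-25
        profile = flexibility_profile(np.arange(1, 31), rmsf)
        assert find_flexible_regions(profile) == [(1, 5), (23, 25)]
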