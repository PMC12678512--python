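import numpy as np
import pytest

from sapflex.conformation import ConformationSeries, conformation_series
from sapflex.landscape import (
    ThermoParams,
    bin_states,
    find_minima,
    free_energy,
    pool_counts,
    select_window,
)
from sapflex.synthetic import HingeModelParams, simulate_hinge_trajectory


def make_series(n, timestep=1.0):
    return ConformationSeries(
        d1=np.linspace(10, 20, n),
        d2=np.linspace(10, 20, n),
        d_cys=np.full(n, 9.0),
        labels=np.array(["other"] * n),
        timestep=timestep,
    )


class TestSelectWindow:
    def test_final_window_retained(self):
        series = make_series(1000)  # 1000 ns at 1 ns/frame
        trimmed = select_window(series, 500.0)
        assert trimmed.n_frames == 500
        assert trimmed.d1[0] == pytest.approx(make_series(1000).d1[500])

    def test_window_equal_to_length_is_identity(self):
        series = make_series(200)
        trimmed = select_window(series, 200.0)
        assert trimmed.n_frames == 200

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            select_window(make_series(100), 0.0)

    def test_too_short_series_rejected_with_hint(self):
        with pytest.raises(ValueError, match="full"):
            select_window(make_series(100), 500.0)


class TestBinStates:
    def test_identical_frames_one_bin(self):
        binned = bin_states(np.full(50, 15.03), np.full(50, 14.42), 0.1)
        assert binned.counts.sum() == 50
        assert (binned.counts > 0).sum() == 1
        assert binned.counts.max() == 50

    def test_half_open_bin_semantics(self):
        # 10.02 and 10.07 fall in the same anchored [10.0, 10.1) bin
        binned = bin_states([10.02, 10.07], [5.01, 5.09], 0.1)
        assert (binned.counts > 0).sum() == 1

    def test_anchoring_is_data_independent(self):
        b1 = bin_states([10.02], [5.0], 0.1)
        b2 = bin_states([10.08, 17.0], [5.0, 5.0], 0.1)
        assert b1.d1_edges[0] == pytest.approx(b2.d1_edges[0])

    def test_constructed_lattice_fills_400_bins(self):
        # one point at each center of a 20 x 20 grid of 0.1 A bins
        centers = 10.05 + 0.1 * np.arange(20)
        d1, d2 = np.meshgrid(centers, centers, indexing="ij")
        binned = bin_states(d1.ravel(), d2.ravel(), 0.1)
        assert binned.counts.shape == (20, 20)
        assert np.all(binned.counts == 1)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            bin_states([], [], 0.1)


class TestFreeEnergy:
    def test_single_bin(self):
        fel = free_energy(bin_states([15.0] * 10, [14.0] * 10, 0.1))
        assert fel.P[fel.occupied_mask][0] == pytest.approx(1.0)
        assert fel.dG[fel.occupied_mask][0] == pytest.approx(0.0)

    def test_two_bin_closed_form_rt_ln3(self):
        """P = 0.75/0.25 at 310 K gives a dG gap of RT ln 3."""
        d1 = np.array([15.0] * 3 + [16.0])
        d2 = np.array([14.0] * 4)
        fel = free_energy(bin_states(d1, d2, 0.1), ThermoParams(T=310.0))
        gap = np.nanmax(fel.dG) - np.nanmin(fel.dG)
        expected = 1.9872e-3 * 310.0 * np.log(3.0)
        assert gap == pytest.approx(expected, abs=1e-10)

    def test_pooled_replicates_by_hand(self):
        # replicate A: state a once; replicate B: a once, b twice -> P_a = 0.5
        ra = bin_states([15.0], [14.0], 0.1)
        rb = bin_states([15.0, 16.0, 16.0], [14.0, 14.0, 14.0], 0.1)
        fel = free_energy(pool_counts([ra, rb]))
        df = fel.to_dataframe()
        p_a = df.loc[np.isclose(df.d1_center, 15.05), "P"].item()
        assert p_a == pytest.approx(0.5)

    def test_probability_conservation(self, fast_switching):
        traj, _ = fast_switching
        series = conformation_series(traj)
        halves = [
            bin_states(series.d1[:300], series.d2[:300], 0.1),
            bin_states(series.d1[300:], series.d2[300:], 0.1),
        ]
        fel = free_energy(pool_counts(halves))
        assert fel.P[fel.occupied_mask].sum() == pytest.approx(1.0, abs=1e-12)

    def test_dg_invariant_to_count_scaling(self):
        binned = bin_states([15.0, 15.0, 16.0], [14.0] * 3, 0.1)
        fel1 = free_energy(binned)
        scaled = bin_states([15.0] * 6 + [16.0] * 3, [14.0] * 9, 0.1)
        fel2 = free_energy(scaled)
        np.testing.assert_allclose(
            fel1.dG[fel1.occupied_mask], fel2.dG[fel2.occupied_mask], atol=1e-12
        )

    def test_monotone_duality_counts_vs_dg(self, fast_switching):
        traj, _ = fast_switching
        series = conformation_series(traj)
        fel = free_energy(bin_states(series.d1, series.d2, 0.5))
        counts = fel.counts[fel.occupied_mask]
        dG = fel.dG[fel.occupied_mask]
        for i in range(len(counts)):
            higher = counts > counts[i]
            assert np.all(dG[higher] < dG[i] + 1e-12)

    def test_unoccupied_bins_are_nan_not_infinite(self):
        fel = free_energy(bin_states([15.0, 18.0], [14.0, 14.0], 0.1))
        assert np.isnan(fel.dG[~fel.occupied_mask]).all()
        assert np.isfinite(fel.dG[fel.occupied_mask]).all()


class TestFindMinima:
    def test_single_occupied_bin(self):
        fel = free_energy(bin_states([15.0] * 5, [14.0] * 5, 0.1))
        minima = find_minima(fel)
        assert len(minima) == 1
        assert minima[0][2] == pytest.approx(0.0)

    def test_bowl_has_single_center_minimum(self):
        d1, d2 = [], []
        for i in range(5):
            for j in range(5):
                depth = 10 - (abs(i - 2) + abs(j - 2)) * 2  # peaked at center
                d1 += [10.05 + 0.1 * i] * depth
                d2 += [20.05 + 0.1 * j] * depth
        fel = free_energy(bin_states(d1, d2, 0.1))
        minima = find_minima(fel)
        assert len(minima) == 1
        assert minima[0][:2] == (pytest.approx(10.25), pytest.approx(20.25))

    def test_two_constructed_basins(self):
        d1, d2 = [], []
        for center in (12.0, 25.0):
            for i in range(3):
                for j in range(3):
                    depth = 5 - (abs(i - 1) + abs(j - 1))
                    d1 += [center + 0.1 * i] * depth
                    d2 += [center + 0.1 * j] * depth
        fel = free_energy(bin_states(d1, d2, 0.1))
        assert len(find_minima(fel)) == 2

    def test_markov_occupancy_recovery(self):
        """Basin-aggregated probabilities match the chain's stationary law."""
        params = HingeModelParams(
            n_frames=10_000, seed=9, rate_open_to_closed=0.5, rate_closed_to_open=0.5
        )
        traj, truth = simulate_hinge_trajectory(params)
        series = conformation_series(traj)
        fel = free_energy(bin_states(series.d1, series.d2, 0.1))
        df = fel.to_dataframe()
        p_open = df.loc[df.d1_center >= 20.0, "P"].sum()
        pi_open = truth.stationary_occupancy[0]
        se = np.sqrt(pi_open * (1 - pi_open) / params.n_frames)
        assert abs(p_open - pi_open) < 3 * se
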