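import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from spatialtuning.maps import (RateMap, TuningCurve, mean_vector, rate_map,
                                spatial_information, tuning_curve)
from spatialtuning.session import SpikeTrain
from spatialtuning.synthetic import HDCellParams, simulate_hd_cell
from conftest import make_session


def _flat_cell(traj, rate_hz, seed):
    p = HDCellParams(pfd=0.0, kappa_tuning=0.0, peak_rate=rate_hz, baseline_rate=rate_hz)
    return simulate_hd_cell(traj, p, seed=seed)


def _curve_from_rates(rates, occupancy=None):
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    centers = np.arange(n) * (360.0 / n) + 180.0 / n
    occ = np.ones(n) if occupancy is None else np.asarray(occupancy, float)
    return TuningCurve(bin_centers=centers, rates=rates, rates_raw=rates,
                       occupancy=occ, n_spikes=int(np.sum(rates * occ)))


def _map_from_arrays(rates, occupancy, bin_size=2.5):
    rates = np.asarray(rates, dtype=float)
    return RateMap(bin_size=bin_size, origin=(0.0, 0.0), rates=rates,
                   rates_raw=rates, occupancy=np.asarray(occupancy, float),
                   n_spikes=int(np.nansum(rates * occupancy)))


class TestTuningCurve:
    def test_flat_rate_cell_recovers_flat_curve(self, octagon, traj1200):
        st_ = _flat_cell(traj1200, 5.0, seed=21)
        sess = make_session(traj1200, st_, octagon)
        tc = tuning_curve(sess, st_)
        # smoothed per-bin sampling error is ~0.27 Hz here, so 0.5 Hz is a
        # ~1.9 sigma band (expected coverage ~94%); check bulk coverage, a
        # 3 sigma cap on the extremes, and the overall level tightly
        dev = np.abs(tc.rates - 5.0)
        assert np.mean(dev <= 0.5) >= 0.85
        assert dev.max() <= 1.0
        assert tc.rates.mean() == pytest.approx(5.0, abs=0.15)

    def test_zero_spikes_gives_zero_curve(self, octagon, traj600):
        st_ = SpikeTrain(np.empty(0), unit_id="mute")
        sess = make_session(traj600, st_, octagon)
        tc = tuning_curve(sess, st_)
        assert tc.n_spikes == 0
        assert np.all(tc.rates == 0)

    def test_spike_count_conservation_and_occupancy(self, octagon, traj600):
        st_ = _flat_cell(traj600, 3.0, seed=22)
        sess = make_session(traj600, st_, octagon)
        tc = tuning_curve(sess, st_)
        assert np.sum(tc.rates_raw * tc.occupancy) == pytest.approx(tc.n_spikes)
        assert np.sum(tc.occupancy) == pytest.approx(traj600.duration,
                                                     abs=traj600.dt + 1e-9)


class TestMeanVector:
    def test_point_mass_bin(self):
        rates = np.zeros(360)
        rates[90] = 7.0  # bin centered at 90.5 deg
        stats = mean_vector(_curve_from_rates(rates))
        assert stats.r == pytest.approx(1.0)
        assert stats.mean_direction == pytest.approx(90.5)

    def test_uniform_curve_has_zero_resultant(self):
        stats = mean_vector(_curve_from_rates(np.full(360, 2.0)))
        assert stats.r == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_curve_matches_bessel_ratio(self):
        theta = np.deg2rad(np.arange(360) + 0.5)
        rates = np.exp(2.0 * (np.cos(theta) - 1.0))
        stats = mean_vector(_curve_from_rates(rates))
        expected = special.i1(2.0) / special.i0(2.0)  # ~0.6978
        assert stats.r == pytest.approx(expected, abs=1e-4)

    def test_all_zero_curve_flagged_undefined(self):
        stats = mean_vector(_curve_from_rates(np.zeros(360)))
        assert not stats.defined
        assert np.isnan(stats.r)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.integers(min_value=0, max_value=359))
    def test_rotation_equivariance(self, shift):
        rng = np.random.default_rng(5)
        rates = rng.uniform(0.1, 10.0, 360)
        base = mean_vector(_curve_from_rates(rates))
        rot = mean_vector(_curve_from_rates(np.roll(rates, shift)))
        assert rot.r == pytest.approx(base.r, abs=1e-10)
        assert (rot.mean_direction - base.mean_direction) % 360 == pytest.approx(
            shift % 360, abs=1e-6)


class TestRateMap:
    def test_flat_cell_recovers_flat_map(self, octagon, traj1200):
        st_ = _flat_cell(traj1200, 5.0, seed=23)
        sess = make_session(traj1200, st_, octagon)
        rm = rate_map(sess, st_)
        # thinly occupied edge bins keep ~1 Hz of sampling error after
        # smoothing; check the bulk at 1 Hz and the overall level tightly
        dev = np.abs(rm.rates[rm.valid] - 5.0)
        assert np.mean(dev <= 1.0) >= 0.95
        assert np.nanmean(rm.rates[rm.valid]) == pytest.approx(5.0, abs=0.2)

    def test_bins_outside_arena_invalid(self, octagon, traj600):
        st_ = _flat_cell(traj600, 2.0, seed=24)
        sess = make_session(traj600, st_, octagon)
        rm = rate_map(sess, st_)
        # the corner bins of the bounding box lie outside the octagon
        assert np.isnan(rm.rates[0, 0]) and np.isnan(rm.rates[-1, -1])

    def test_conservation_before_smoothing(self, octagon, traj600):
        st_ = _flat_cell(traj600, 4.0, seed=25)
        sess = make_session(traj600, st_, octagon)
        rm = rate_map(sess, st_)
        v = rm.valid
        assert np.sum(rm.rates_raw[v] * rm.occupancy[v]) == pytest.approx(rm.n_spikes)

    def test_insufficient_sampling_raises(self, octagon, straight_trajectory):
        st_ = SpikeTrain(np.array([0.5]))
        sess = make_session(straight_trajectory, st_, octagon)
        with pytest.raises(ValueError, match="insufficient spatial sampling"):
            rate_map(sess, st_, min_occ=10.0)


class TestSpatialInformation:
    def test_uniform_map_zero_bits(self):
        rm = _map_from_arrays(np.full((8, 8), 3.0), np.full((8, 8), 1.0))
        assert spatial_information(rm) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_firing_log2_n(self):
        rates = np.zeros((8, 8))
        rates[3, 4] = 64.0
        rm = _map_from_arrays(rates, np.full((8, 8), 1.0))
        assert spatial_information(rm) == pytest.approx(6.0, abs=1e-12)

    def test_matches_direct_formula_on_small_fixture(self):
        # frozen 5x5 occupancy / rate fixture
        occ = np.array([[1.0, 2.0, 0.5, 1.5, 1.0],
                        [2.0, 1.0, 1.0, 0.5, 2.5],
                        [0.5, 1.5, 3.0, 1.0, 1.0],
                        [1.0, 1.0, 0.5, 2.0, 1.5],
                        [2.0, 0.5, 1.0, 1.0, 1.0]])
        rates = np.array([[0.0, 1.0, 4.0, 0.5, 0.0],
                          [2.0, 8.0, 3.0, 1.0, 0.2],
                          [0.1, 5.0, 9.0, 2.0, 0.0],
                          [0.0, 2.0, 4.0, 1.0, 0.3],
                          [0.0, 0.0, 1.0, 0.5, 0.0]])
        rm = _map_from_arrays(rates, occ)
        p = occ / occ.sum()
        lam_bar = np.sum(p * rates)
        direct = sum(p[i, j] * (rates[i, j] / lam_bar) * np.log2(rates[i, j] / lam_bar)
                     for i in range(5) for j in range(5) if rates[i, j] > 0)
        assert spatial_information(rm) == pytest.approx(direct, abs=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_under_rate_scaling(self, scale):
        rng = np.random.default_rng(8)
        rates = rng.uniform(0, 5, (6, 6))
        occ = rng.uniform(0.5, 2, (6, 6))
        si1 = spatial_information(_map_from_arrays(rates, occ))
        si2 = spatial_information(_map_from_arrays(rates * scale, occ))
        assert si2 == pytest.approx(si1, rel=1e-9)

    def test_increases_when_firing_concentrates(self):
        # same total spikes into fewer equally occupied bins -> SI rises
        n = 64
        occ = np.full((8, 8), 1.0)
        prev = -1.0
        for k in (32, 16, 8, 4, 2, 1):
            rates = np.zeros(n)
            rates[:k] = n / k
            si = spatial_information(_map_from_arrays(rates.reshape(8, 8), occ))
            assert si > prev
            prev = si

    def test_zero_mean_rate_raises(self):
        rm = _map_from_arrays(np.zeros((5, 5)), np.ones((5, 5)))
        with pytest.raises(ValueError, match="zero mean rate"):
            spatial_information(rm)


class TestWriters:
    def test_tuning_curve_csv_round_trip(self, tmp_path):
        import pandas as pd
        from spatialtuning.maps import write_tuning_curve
        tc = _curve_from_rates(np.arange(360.0))
        write_tuning_curve(tc, tmp_path / "tc.csv")
        back = pd.read_csv(tmp_path / "tc.csv")
        assert list(back.columns) == ["bin_deg", "rate_hz", "occ_s"]
        np.testing.assert_allclose(back["rate_hz"], tc.rates, atol=1e-6)

    def test_rate_map_grid_and_sidecar(self, tmp_path):
        import json
        from spatialtuning.maps import write_rate_map
        rm = _map_from_arrays(np.ones((4, 6)), np.ones((4, 6)))
        write_rate_map(rm, tmp_path / "rm.csv")
        grid = np.loadtxt(tmp_path / "rm.csv", delimiter=",")
        assert grid.shape == (4, 6)
        meta = json.loads((tmp_path / "rm.csv.meta.json").read_text())
        assert meta["bin_size_cm"] == 2.5


class TestTuningSharpness:
    def test_resultant_grows_with_concentration(self, octagon, traj1200):
        rs = []
        for i, kappa in enumerate([0.5, 1.0, 2.0, 4.0, 8.0]):
            p = HDCellParams(pfd=120.0, kappa_tuning=kappa, peak_rate=30.0,
                             baseline_rate=0.5)
            st_ = simulate_hd_cell(traj1200, p, seed=100 + i)
            sess = make_session(traj1200, st_, octagon)
            rs.append(mean_vector(tuning_curve(sess, st_)).r)
        assert all(b > a for a, b in zip(rs, rs[1:]))
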