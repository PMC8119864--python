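import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialtuning.maps import RateMap, TuningCurve, tuning_curve
from spatialtuning.rotation import (adjacent_compartment_shifts,
                                    classify_field_barrier_relation,
                                    classify_rotation_response,
                                    compartment_tuning_curves, map_rotation_shift,
                                    normalize_shift_sign, tuning_shift)
from spatialtuning.session import SpikeTrain
from spatialtuning.synthetic import (CueManipulation, HDCellParams, PlaceCellParams,
                                     apply_manipulation, build_geometry,
                                     compartment_axis_angles, simulate_hd_cell,
                                     simulate_hd_cell_by_region, simulate_place_cell,
                                     simulate_trajectory)
from conftest import make_session


def _curve(rates):
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    return TuningCurve(bin_centers=np.arange(n) * (360.0 / n) + 180.0 / n,
                       rates=rates, rates_raw=rates, occupancy=np.ones(n),
                       n_spikes=int(rates.sum()))


def _brute_force_profile(a, b):
    """Independent oracle: explicit per-shift Pearson correlation loop."""
    n = len(a)
    return np.array([np.corrcoef(np.roll(a, s), b)[0, 1] for s in range(n)])


class TestTuningShift:
    def test_self_shift_zero_corr_one(self):
        rng = np.random.default_rng(1)
        tc = _curve(rng.uniform(0, 10, 360))
        res = tuning_shift(tc, tc)
        assert res.shift == 0.0
        assert res.max_corr == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("shift_bins", [90, -90, 45, 179, 180])
    def test_recovers_constructed_circular_shift(self, shift_bins):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, 360)
        b = np.roll(a, shift_bins)  # b[i] = a[i - s] -> tuning moved by +s deg
        res = tuning_shift(_curve(a), _curve(b))
        expected = (shift_bins + 180) % 360 - 180
        if expected == -180:
            expected = 180
        assert res.shift == expected
        assert res.max_corr == pytest.approx(1.0, abs=1e-12)

    def test_profile_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 5, 360), rng.uniform(0, 5, 360)
        res = tuning_shift(_curve(a), _curve(b))
        np.testing.assert_allclose(res.profile, _brute_force_profile(a, b), atol=1e-10)

    def test_constant_curve_raises(self):
        with pytest.raises(ValueError, match="degenerate curve"):
            tuning_shift(_curve(np.full(360, 2.0)), _curve(np.arange(360.0)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _curve(rng.uniform(0, 5, 360)), _curve(rng.uniform(0, 5, 360))
        s_ab = tuning_shift(a, b).shift
        s_ba = tuning_shift(b, a).shift
        assert (s_ab + s_ba) % 360 in (0.0, 360.0) or abs(s_ab) == 180.0

    def test_simulated_rotation_recovered(self, octagon):
        p = HDCellParams(pfd=100.0, kappa_tuning=4.0, peak_rate=30.0)
        q, _ = apply_manipulation(p, CueManipulation(90.0, 1.0, 0.0))
        ta = simulate_trajectory(octagon, 600.0, seed=41)
        tb = simulate_trajectory(octagon, 600.0, seed=42)
        sa = simulate_hd_cell(ta, p, seed=43)
        sb = simulate_hd_cell(tb, q, seed=44)
        res = tuning_shift(tuning_curve(make_session(ta, sa, octagon), sa),
                           tuning_curve(make_session(tb, sb, octagon), sb))
        assert abs(res.shift - 90.0) <= 6.0


class TestMapRotationShift:
    def test_session_vs_itself(self, octagon, traj600):
        p = PlaceCellParams(center=(15.0, 0.0), peak_rate=15.0)
        st_ = simulate_place_cell(traj600, p, seed=50, unit_id="pc")
        sess = make_session(traj600, st_, octagon)
        res = map_rotation_shift(sess, sess, "pc")
        assert res.shift == 0.0
        assert res.max_corr == pytest.approx(1.0, abs=1e-9)

    def test_rotated_field_recovered_exactly_on_grid(self, octagon):
        p = PlaceCellParams(center=(20.0, 0.0), peak_rate=15.0)
        q, delta = apply_manipulation(p, CueManipulation(90.0, 1.0, 0.0))
        ta = simulate_trajectory(octagon, 600.0, seed=51)
        tb = simulate_trajectory(octagon, 600.0, seed=52)
        sa = simulate_place_cell(ta, p, seed=53, unit_id="pc")
        sb = simulate_place_cell(tb, q, seed=54, unit_id="pc")
        res = map_rotation_shift(make_session(ta, sa, octagon),
                                 make_session(tb, sb, octagon), "pc")
        assert res.shift == 90.0

    def test_profile_at_zero_equals_plain_map_correlation(self, octagon, traj600):
        p = PlaceCellParams(center=(-10.0, 10.0), peak_rate=12.0)
        ta = traj600
        tb = simulate_trajectory(octagon, 600.0, seed=55)
        sa = simulate_place_cell(ta, p, seed=56, unit_id="pc")
        sb = simulate_place_cell(tb, p, seed=57, unit_id="pc")
        res = map_rotation_shift(make_session(ta, sa, octagon),
                                 make_session(tb, sb, octagon), "pc")
        assert res.profile[0] == pytest.approx(res.max_corr, abs=1e-9) or \
            res.profile[0] <= res.max_corr
        assert res.angles[0] == 0.0
        assert res.n_overlap >= 20


@pytest.fixture(scope="module")
def radial():
    return build_geometry("radial4")


@pytest.fixture(scope="module")
def radial_traj(radial):
    return simulate_trajectory(radial, 1200.0, seed=60)


@pytest.fixture(scope="module")
def barrier_geom():
    return build_geometry("octagon_barrier")  # barrier along the y axis


class TestCompartments:
    def test_corridor_only_cell_flagged(self, radial, radial_traj):
        # a cell that never fires: all compartments have 0 spikes -> unusable
        st_ = SpikeTrain(np.empty(0), unit_id="mute")
        sess = make_session(radial_traj, st_, radial)
        with pytest.raises(ValueError, match="no usable compartments"):
            compartment_tuning_curves(sess, "mute")

    def test_global_reference_shifts_near_zero(self, radial, radial_traj):
        p = HDCellParams(pfd=250.0, kappa_tuning=4.0, peak_rate=30.0)
        st_ = simulate_hd_cell(radial_traj, p, seed=61, unit_id="hd")
        sess = make_session(radial_traj, st_, radial)
        curves, usable = compartment_tuning_curves(sess, "hd")
        assert all(usable)
        shifts = adjacent_compartment_shifts(curves, usable)
        for s in shifts.shifts:
            assert abs(s) <= 6.0
        assert abs(shifts.mean_shift) <= 6.0

    def test_local_reference_shifts_near_60(self, radial, radial_traj):
        p = HDCellParams(pfd=10.0, kappa_tuning=4.0, peak_rate=30.0)
        axes = compartment_axis_angles("radial4")
        pfd_by_region = {f"compartment_{j+1}": (10.0 + axes[j] - axes[0]) % 360
                         for j in range(4)}
        st_ = simulate_hd_cell_by_region(radial_traj, radial, pfd_by_region, p,
                                         seed=62, unit_id="hd")
        sess = make_session(radial_traj, st_, radial)
        curves, usable = compartment_tuning_curves(sess, "hd")
        shifts = adjacent_compartment_shifts(curves, usable)
        for s in shifts.shifts:
            if s is not None:
                assert abs(s - 60.0) <= 6.0

    def test_identical_and_constructed_shifts(self):
        rng = np.random.default_rng(63)
        base = rng.uniform(0, 10, 360)
        same = [_curve(base) for _ in range(4)]
        res = adjacent_compartment_shifts(same, [True] * 4)
        assert res.shifts == (0.0, 0.0, 0.0)
        assert res.mean_shift == 0.0
        rolled = [_curve(np.roll(base, 60 * k)) for k in range(4)]
        res = adjacent_compartment_shifts(rolled, [True] * 4)
        assert res.shifts == (60.0, 60.0, 60.0)
        assert res.mean_shift == pytest.approx(60.0)

    def test_mixed_shifts_match_pairwise_oracle(self):
        rng = np.random.default_rng(64)
        curves = [_curve(rng.uniform(0, 10, 360)) for _ in range(4)]
        res = adjacent_compartment_shifts(curves, [True] * 4)
        for j in range(3):
            prof = _brute_force_profile(curves[j].rates, curves[j + 1].rates)
            best = np.flatnonzero(prof >= prof.max() - 1e-12)
            signed = (best + 180) % 360 - 180
            assert res.shifts[j] in set(np.where(signed == -180, 180, signed))


class TestBarrierRelation:
    def _map_with_peak(self, px, py):
        # 40x40 grid of 2.5 cm bins centered on the origin
        rates = np.zeros((40, 40))
        occ = np.ones((40, 40))
        i = int((px + 50.0) / 2.5)
        j = int((py + 50.0) / 2.5)
        rates[i, j] = 10.0
        return RateMap(bin_size=2.5, origin=(-50.0, -50.0), rates=rates,
                       rates_raw=rates, occupancy=occ, n_spikes=10)

    @pytest.mark.parametrize("px,expected", [
        (2.5, "adjacent"),      # ~2 cm from the barrier line
        (45.0, "distant"),
        (10.0, "adjacent"),     # exactly at threshold (inclusive)
    ])
    def test_adjacency(self, barrier_geom, px, expected):
        rm = self._map_with_peak(px - 1.25, 1.25)  # bin center at (px, 2.5-ish)
        assert classify_field_barrier_relation(rm, barrier_geom) == expected

    def test_no_barrier_raises(self, octagon):
        rm = self._map_with_peak(0.0, 0.0)
        with pytest.raises(ValueError, match="no barrier"):
            classify_field_barrier_relation(rm, octagon)


class TestRotationResponse:
    @pytest.mark.parametrize("obs,cmd,expected", [
        (85.0, 90.0, "rotated"),
        (10.0, 90.0, "unchanged"),
        (50.0, 90.0, "other"),
        (60.0, 90.0, "rotated"),     # inclusive rotated window
        (-29.9, 90.0, "unchanged"),  # exclusive unchanged window
        (30.0, 90.0, "other"),       # 30 from zero is outside (<30 strict)
        (-85.0, -90.0, "rotated"),
    ])
    def test_windows(self, obs, cmd, expected):
        assert classify_rotation_response(obs, cmd) == expected

    def test_overlapping_windows_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_rotation_response(10.0, 45.0)

    def test_sign_normalization(self):
        assert normalize_shift_sign(-90.0, -90.0) == 90.0
        assert normalize_shift_sign(90.0, 90.0) == 90.0
        assert normalize_shift_sign(-10.0, -90.0) == 10.0
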