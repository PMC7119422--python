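"""Polar transformation, radial profiles and the 15-feature vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spheropol as sp
from spheropol.radial_features import (
    marker_deltas,
    nuclear_initial_slope,
    polar_radius,
    radial_profile,
    radius_at_fraction,
)
from spheropol.types import RadialProfile


def naive_radial_profile(proj, com, r_max):
    """Per-pixel double-loop oracle; no vectorised shortcut."""
    sums = [0.0] * (r_max + 1)
    counts = [0] * (r_max + 1)
    h, w = proj.shape
    for y in range(h):
        for x in range(w):
            r = polar_radius(x, y, com)
            if r <= r_max:
                sums[r] += proj[y, x]
                counts[r] += 1
    mean = np.array([s / c if c else 0.0 for s, c in zip(sums, counts)])
    total = mean.sum()
    cum = np.cumsum(mean) / total
    return mean, cum


class TestPolarRadius:
    @pytest.mark.parametrize(
        "xy, com, expected",
        [
            ((5.0, 5.0), (5.0, 5.0), 0),  # pixel at the centre
            ((3, 4), (0.0, 0.0), 5),  # pythagorean triple
            ((2, 1), (0.0, 0.0), 2),  # sqrt(5) ~ 2.236 rounds down
            ((0, 3), (0.0, 0.5), 3),  # d = 2.5 rounds half away from zero
        ],
    )
    def test_examples(self, xy, com, expected):
        assert polar_radius(xy[0], xy[1], com) == expected

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        xs = rng.integers(0, 50, 100)
        ys = rng.integers(0, 50, 100)
        com = (24.3, 25.7)
        vec = polar_radius(xs, ys, com)
        assert all(vec[i] == polar_radius(int(xs[i]), int(ys[i]), com) for i in range(100))


class TestRadialProfile:
    def test_point_mass_at_centre(self):
        img = np.zeros((21, 21))
        img[10, 10] = 7.0
        prof = radial_profile(img, (10.0, 10.0), r_max=10)
        assert prof.normalized_cumulative[0] == 1.0
        assert np.all(prof.normalized_cumulative == 1.0)

    def test_single_ring_steps_to_one(self):
        img = np.zeros((41, 41))
        yy, xx = np.indices(img.shape)
        r = polar_radius(xx, yy, (20.0, 20.0))
        img[r == 10] = 3.0
        prof = radial_profile(img, (20.0, 20.0), r_max=18)
        assert np.all(prof.normalized_cumulative[:10] == 0.0)
        assert np.all(prof.normalized_cumulative[10:] == 1.0)

    def test_two_equal_rings_split_half(self):
        # per-pixel mean normalisation cancels the circumference growth, so
        # two rings with equal per-pixel intensity split the cumulative 50/50
        img = np.zeros((61, 61))
        yy, xx = np.indices(img.shape)
        r = polar_radius(xx, yy, (30.0, 30.0))
        img[(r == 5) | (r == 15)] = 2.0
        prof = radial_profile(img, (30.0, 30.0), r_max=25)
        assert prof.normalized_cumulative[5] == pytest.approx(0.5)
        assert prof.normalized_cumulative[14] == pytest.approx(0.5)
        assert prof.normalized_cumulative[15] == pytest.approx(1.0)

    def test_matches_naive_double_loop_bit_for_bit(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            proj = rng.uniform(0, 100, size=(64, 64))
            com = (rng.uniform(25, 40), rng.uniform(25, 40))
            prof = radial_profile(proj, com, r_max=30)
            mean, cum = naive_radial_profile(proj, com, 30)
            assert np.array_equal(prof.mean_intensity_per_radius, mean)
            assert np.array_equal(prof.normalized_cumulative, cum)

    def test_all_zero_channel_is_degenerate_with_warning(self):
        with pytest.warns(UserWarning):
            prof = radial_profile(np.zeros((11, 11)), (5.0, 5.0), r_max=5)
        assert prof.degenerate
        assert np.all(prof.normalized_cumulative == 0.0)


class TestRadiusAtFraction:
    def test_linear_cumulative_returns_fraction(self):
        r_max = 50
        cum = np.arange(r_max + 1) / r_max
        prof = RadialProfile("x", np.ones(r_max + 1), cum)
        assert radius_at_fraction(prof, 0.6) == pytest.approx(0.6)

    def test_hand_interpolated_bracket(self):
        # cumulative 0.5 at relative radius 0.30 and 0.7 at 0.35 -> 0.325
        r_max = 20
        cum = np.minimum(np.arange(r_max + 1) / 10.0, 1.0)
        cum[6] = 0.5
        cum[7] = 0.7
        cum[8:] = 1.0
        prof = RadialProfile("x", np.ones(r_max + 1), cum)
        assert radius_at_fraction(prof, 0.6) == pytest.approx(0.325)

    def test_delta_ring_within_one_bin(self):
        # all intensity on one ring: the readout equals the ring position
        # up to the one-bin interpolation error
        r_max = 50
        mean = np.zeros(r_max + 1)
        mean[20] = 1.0
        cum = np.cumsum(mean)
        prof = RadialProfile("x", mean, cum)
        assert radius_at_fraction(prof, 0.6) == pytest.approx(0.4, abs=1.0 / r_max)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_fraction(self, f1, f2):
        rng = np.random.default_rng(11)
        mean = rng.uniform(0, 1, 31)
        cum = np.cumsum(mean) / mean.sum()
        prof = RadialProfile("x", mean, cum)
        lo, hi = sorted([f1, f2])
        assert radius_at_fraction(prof, lo) <= radius_at_fraction(prof, hi) + 1e-12

    def test_degenerate_profile_raises(self):
        prof = RadialProfile("x", np.zeros(11), np.zeros(11), degenerate=True)
        with pytest.raises(ValueError, match="no signal"):
            radius_at_fraction(prof, 0.6)


class TestNuclearInitialSlope:
    def _profile_with_inner_share(self, share, r_max=100, cutoff_bin=30):
        mean = np.zeros(r_max + 1)
        mean[:cutoff_bin] = share / cutoff_bin if share else 0.0
        mean[cutoff_bin + 20] = 1.0 - share
        cum = np.cumsum(mean) / mean.sum()
        return RadialProfile("nuclei", mean, cum)

    def test_no_signal_inside_cutoff(self):
        prof = self._profile_with_inner_share(0.0)
        assert nuclear_initial_slope(prof, 0.30) == pytest.approx(0.0, abs=1e-9)

    def test_all_signal_inside_cutoff(self):
        r_max = 100
        mean = np.zeros(r_max + 1)
        mean[:25] = 1.0
        cum = np.cumsum(mean) / mean.sum()
        prof = RadialProfile("nuclei", mean, cum)
        assert nuclear_initial_slope(prof, 0.30) == pytest.approx(1 / 0.3)

    def test_half_signal_inside_cutoff(self):
        prof = self._profile_with_inner_share(0.5)
        assert nuclear_initial_slope(prof, 0.30) == pytest.approx(0.5 / 0.3, rel=0.05)


class TestMarkerDeltas:
    @pytest.mark.parametrize(
        "gp58, gp135, actin, f1, f2",
        [
            (0.9, 0.5, 0.5, +0.4, 0.0),  # regular-polarity direction
            (0.5, 0.9, 0.9, -0.4, 0.0),  # inverse direction
            (0.7, 0.5, 0.5, +0.2, 0.0),  # actin colocalised with gp135
        ],
    )
    def test_sign_rule(self, gp58, gp135, actin, f1, f2):
        got1, got2 = marker_deltas(
            {"basolateral": gp58, "apical": gp135, "actin": actin, "nuclei": 0.6}
        )
        assert got1 == pytest.approx(f1)
        assert got2 == pytest.approx(f2)

    def test_rejects_out_of_range_position(self):
        with pytest.raises(ValueError):
            marker_deltas({"basolateral": 1.2, "apical": 0.5, "actin": 0.5, "nuclei": 0.5})


class TestFeatureVectorOnGenerator:
    def test_group1_positive_f1_flat_nuclear_core(self, noiseless_params):
        stack, _ = sp.generate_spheroid("1_regular", noiseless_params, seed=11)
        fv = sp.extract_features(stack)
        assert fv.f1_delta_gp58_gp135 > 0.1
        assert abs(fv.f2_delta_actin_gp135) < 0.05
        assert fv.f9_nuclear_initial_slope < 0.1

    def test_group2_negative_f1(self, noiseless_params):
        stack, _ = sp.generate_spheroid("2_inverse", noiseless_params, seed=11)
        fv = sp.extract_features(stack)
        assert fv.f1_delta_gp58_gp135 < -0.1

    def test_aggregate_nuclei_in_lumen_zone(self, noiseless_params):
        stack, _ = sp.generate_spheroid("3a_aggregate", noiseless_params, seed=11)
        fv = sp.extract_features(stack)
        assert fv.f9_nuclear_initial_slope > 1.0

    def test_identities_and_rotation_invariance(self, small_dataset):
        stack = small_dataset.stacks[0]
        fv = sp.extract_features(stack, n_slices=1)
        assert fv.f1_delta_gp58_gp135 == fv.f3_relpos60_gp58 - fv.f4_relpos60_gp135
        assert fv.f2_delta_actin_gp135 == fv.f5_relpos60_actin - fv.f4_relpos60_gp135

        rotated = sp.SpheroidStack(
            voxels=np.rot90(stack.voxels, k=1, axes=(2, 3)).copy(),
            channel_map=dict(stack.channel_map),
            pixel_size_um=stack.pixel_size_um,
            z_step_um=stack.z_step_um,
            spheroid_id=stack.spheroid_id,
        )
        fv_rot = sp.extract_features(rotated, n_slices=1)
        assert fv_rot.as_array() == pytest.approx(fv.as_array(), abs=1e-9)

    def test_intensity_scaling_invariance_exact(self, small_dataset):
        stack = small_dataset.stacks[1]
        fv = sp.extract_features(stack, n_slices=1)
        scaled = sp.SpheroidStack(
            voxels=stack.voxels * 4.0,  # power of two: float-exact rescaling
            channel_map=dict(stack.channel_map),
            pixel_size_um=stack.pixel_size_um,
            z_step_um=stack.z_step_um,
        )
        fv_scaled = sp.extract_features(scaled, n_slices=1)
        assert np.array_equal(fv.as_array(), fv_scaled.as_array())
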