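"""Rotational morphology: rotation exactness, degeneracies, filters."""

import numpy as np
import pytest

from rotomorph import (
    RMPConfig,
    closing,
    feature_extract,
    make_line_se,
    opening,
    rmp_closing,
    rmp_opening,
    rotate_image,
    smooth,
)


class TestRotation:
    def test_zero_angle_is_identity(self, random_image, config8):
        assert np.array_equal(rotate_image(random_image, 0.0, "cw", config8), random_image)

    def test_180_point_symmetry(self, config8):
        f = np.zeros((17, 17))
        f[8 + 5, 8] = 9.0  # offset (+5, 0) from center
        g = rotate_image(f, 180.0, "cw", config8)
        assert g[8 - 5, 8] == 9.0
        assert g.sum() == 9.0

    @pytest.mark.parametrize("interp", ["nearest", "bilinear"])
    @pytest.mark.parametrize("angle", [90.0, 180.0, 270.0])
    def test_quarter_turns_lossless_roundtrip(self, random_image, angle, interp):
        cfg = RMPConfig(interpolation=interp)
        g = rotate_image(random_image, angle, "cw", cfg)
        back = rotate_image(g, angle, "ccw", cfg)
        assert np.array_equal(back, random_image)
        # a permutation preserves the multiset of values
        assert np.array_equal(np.sort(g.ravel()), np.sort(random_image.ravel()))

    def test_angles_cover_half_turn(self):
        cfg = RMPConfig(n_directions=4)
        assert cfg.angles.tolist() == [0.0, 45.0, 90.0, 135.0]

    def test_invalid_direction(self, random_image):
        with pytest.raises(ValueError):
            rotate_image(random_image, 10.0, "widdershins")


class TestRMPDegeneracies:
    def test_single_direction_equals_plain_operators(self, random_image, se_line41):
        se = make_line_se(5)
        cfg = RMPConfig(n_directions=1)
        assert np.array_equal(rmp_opening(random_image, se, cfg), opening(random_image, se))
        assert np.array_equal(rmp_closing(random_image, se, cfg), closing(random_image, se))

    def test_two_directions_equal_perpendicular_branch(self, random_image):
        """With N=2 the 90-degree branch is exactly the vertical-line filter."""
        se_h = make_line_se(5)
        se_v = make_line_se(5, angle=90)
        cfg = RMPConfig(n_directions=2)
        expected_open = np.maximum(opening(random_image, se_h), opening(random_image, se_v))
        expected_close = np.minimum(closing(random_image, se_h), closing(random_image, se_v))
        assert np.array_equal(rmp_opening(random_image, se_h, cfg), expected_open)
        assert np.array_equal(rmp_closing(random_image, se_h, cfg), expected_close)

    @pytest.mark.parametrize("n", [1, 2, 4, 8])
    def test_constants_are_fixed_points(self, n):
        f = np.full((24, 24), 7.0)
        se = make_line_se(7)
        cfg = RMPConfig(n_directions=n)
        # fixed to machine epsilon: interpolation weights at oblique
        # angles sum to 1 only within floating-point rounding
        assert np.allclose(rmp_opening(f, se, cfg), f, rtol=0, atol=1e-12)
        assert np.allclose(rmp_closing(f, se, cfg), f, rtol=0, atol=1e-12)
        assert np.allclose(smooth(f, se, cfg), f, rtol=0, atol=1e-12)

    def test_invalid_n_directions(self):
        with pytest.raises(ValueError):
            RMPConfig(n_directions=0)


class TestSmoothing:
    def test_compositional_definition(self, random_image, config8):
        """SM(f) is exactly the average of the open-close / close-open chains."""
        se = make_line_se(5)
        oc = rmp_opening(rmp_closing(random_image, se, config8), se, config8)
        co = rmp_closing(rmp_opening(random_image, se, config8), se, config8)
        assert np.allclose(smooth(random_image, se, config8), 0.5 * oc + 0.5 * co,
                           rtol=0, atol=1e-12)

    def test_small_bump_removed(self, config8):
        """A bump narrower than the SE vanishes from the smoothed image."""
        from scipy import ndimage

        f = np.full((96, 96), 100.0)
        bump = np.zeros_like(f)
        bump[48, 48] = 1.0
        bump = ndimage.gaussian_filter(bump, 2.0)
        f = f + bump * (20.0 / bump.max())  # base ~ 11 px, amplitude 20
        sm = smooth(f, make_line_se(41), config8)
        assert np.abs(sm - 100.0).max() < 0.5


class TestFeatureExtract:
    def test_constant_maps_to_zero(self, config8):
        f = np.full((32, 32), 200.0)
        out = feature_extract(f, make_line_se(9), config8)
        assert out.min() == 0.0
        assert np.allclose(out, 0.0, rtol=0, atol=1e-12)

    def test_minimum_exactly_zero(self, rng, config8):
        f = rng.integers(0, 256, size=(48, 48)).astype(float)
        out = feature_extract(f, make_line_se(9), config8)
        assert out.min() == 0.0

    def test_spike_location_is_argmax(self, config8):
        """An isolated spike on a smoothing-invariant background peaks in the output."""
        f = np.full((64, 64), 50.0)
        f[30, 33] = 90.0
        out = feature_extract(f, make_line_se(21), config8)
        assert np.unravel_index(np.argmax(out), out.shape) == (30, 33)

    def test_offset_invariance(self, rng, config8):
        """Adding a constant to the input leaves the shifted feature image unchanged."""
        f = rng.integers(0, 200, size=(40, 40)).astype(float)
        se = make_line_se(9)
        a = feature_extract(f, se, config8)
        b = feature_extract(f + 17.0, se, config8)
        assert np.allclose(a, b, rtol=0, atol=1e-9)

    def test_bipolar_peaks_straddle_background_level(self, config8):
        """Bright and dark peaks end up above and below the flat level."""
        f = np.full((64, 96), 100.0)
        f[30:33, 20:23] = 140.0   # bright target
        f[30:33, 70:73] = 60.0    # dark target
        out = feature_extract(f, make_line_se(21), config8)
        level = out[5, 5]  # far from both peaks
        assert out[31, 21] > level
        assert out[31, 71] < level


class TestSizeSelectivity:
    def test_response_energy_vs_se_length(self, config8):
        """Disk response is strong for d < L and collapses once d >> L."""
        from scipy import ndimage

        f = np.full((96, 96), 100.0)
        s, t = np.mgrid[-48:48, -48:48]
        f += np.where(s * s + t * t <= 10.5**2, 25.0, 0.0)
        f = ndimage.gaussian_filter(f, 1.0)
        energies = []
        for length in (41, 31, 9):
            d = feature_extract(f, make_line_se(length), config8, shift_min=False)
            energies.append(float(np.sum(d[28:68, 28:68] ** 2)))
        big, mid, small = energies
        assert big > 10 * small  # d=21 disk: L=41 extracts, L=9 cannot
        assert big >= mid >= small
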