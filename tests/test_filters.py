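"""Unit and property tests for the denoising filters."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from mrnlm import (
    BilateralParams,
    MRNLMParams,
    MultiReconSet,
    NLMParams,
    ParameterError,
    PatchSpec,
    Volume,
    bilateral_filter,
    gaussian_filter,
    mr_average,
    mrnlm_filter,
    nlm_filter,
    nlm_weight,
    patch_distance2,
)

from _reference import naive_bilateral, naive_mrnlm, naive_nlm


# ---------------------------------------------------------------------------
# primitives


class TestPatchDistance:
    def test_identical_patches_are_at_distance_zero(self, small_volume):
        assert patch_distance2(small_volume, (4, 4, 2), small_volume, (4, 4, 2), PatchSpec()) == 0.0

    def test_single_voxel_patch_is_squared_difference(self):
        a = Volume(np.full((3, 3, 1), 3.0))
        b = Volume(np.full((3, 3, 1), 1.0))
        d = patch_distance2(a, (1, 1, 0), b, (1, 1, 0), PatchSpec((0, 0, 0)))
        assert d == pytest.approx(4.0)

    def test_matches_naive_double_loop(self, rng, small_volume):
        """5x5 in-plane patches agree with an explicit sum over voxel pairs."""
        other = Volume(rng.random(small_volume.shape), small_volume.spacing)
        radius = (2, 2, 0)
        ca, cb = (3, 4, 1), (6, 2, 3)
        pad_a = np.pad(small_volume.data, [(r, r) for r in radius], mode="reflect")
        pad_b = np.pad(other.data, [(r, r) for r in radius], mode="reflect")
        expected = 0.0
        for k in itertools.product(*(range(2 * r + 1) for r in radius)):
            fa = pad_a[tuple(c + o for c, o in zip(ca, k))]
            fb = pad_b[tuple(c + o for c, o in zip(cb, k))]
            expected += (fa - fb) ** 2
        got = patch_distance2(small_volume, ca, other, cb, PatchSpec(radius))
        assert got == pytest.approx(expected, rel=1e-12)
        # symmetric in its (volume, centre) arguments
        assert got == pytest.approx(
            patch_distance2(other, cb, small_volume, ca, PatchSpec(radius)), rel=1e-12
        )

    def test_center_out_of_bounds(self, small_volume):
        with pytest.raises(IndexError):
            patch_distance2(small_volume, (9, 0, 0), small_volume, (0, 0, 0), PatchSpec())


class TestNLMWeight:
    @pytest.mark.parametrize(
        "dist2, h, expected",
        [
            (0.0, 0.7, 1.0),
            (0.49, 0.7, math.exp(-1.0)),
            (1e9, 0.01, 0.0),  # underflows cleanly to zero
        ],
    )
    def test_values(self, dist2, h, expected):
        assert nlm_weight(dist2, h) == pytest.approx(expected, abs=1e-12)

    def test_invalid_h(self):
        with pytest.raises(ParameterError):
            nlm_weight(1.0, 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        d1=st.floats(0, 50), d2=st.floats(0, 50), h=st.floats(0.01, 10)
    )
    def test_monotone_decreasing_in_distance(self, d1, d2, h):
        lo, hi = sorted([d1, d2])
        w_lo, w_hi = nlm_weight(lo, h), nlm_weight(hi, h)
        assert 0.0 <= w_hi <= w_lo <= 1.0


# ---------------------------------------------------------------------------
# oracle equivalence and identities


class TestNLMFilter:
    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((7, 7, 3), 4.2), (2, 2, 3))
        out = nlm_filter(vol, NLMParams(h=0.5, search_radius=(2, 2, 1)))
        np.testing.assert_allclose(out.data, 4.2, rtol=1e-12)

    def test_zero_search_radius_is_identity(self, small_volume):
        out = nlm_filter(small_volume, NLMParams(h=0.2, search_radius=(0, 0, 0)))
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_matches_naive_loop(self, small_volume):
        params = NLMParams(h=0.4, patch=PatchSpec((1, 1, 1)), search_radius=(2, 2, 1))
        got = nlm_filter(small_volume, params)
        want = naive_nlm(small_volume, 0.4, (1, 1, 1), (2, 2, 1))
        np.testing.assert_allclose(got.data, want.data, rtol=1e-10)

    def test_output_in_search_window_hull(self, rng):
        """Each voxel is a convex combination of its clipped window values."""
        vol = Volume(rng.random((10, 8, 6)) * 5, (2, 2, 3))
        rs = (2, 2, 1)
        out = nlm_filter(vol, NLMParams(h=0.15, search_radius=rs))
        size = tuple(2 * r + 1 for r in rs)
        hi = ndimage.maximum_filter(vol.data, size=size, mode="nearest")
        lo = ndimage.minimum_filter(vol.data, size=size, mode="nearest")
        assert np.all(out.data <= hi + 1e-10)
        assert np.all(out.data >= lo - 1e-10)


class TestMRNLMFilter:
    @pytest.mark.parametrize("include_target", [True, False])
    def test_identical_auxiliaries_give_identity(self, small_volume, include_target):
        recons = MultiReconSet(small_volume, (small_volume, small_volume, small_volume))
        out = mrnlm_filter(recons, MRNLMParams(h=0.1, include_target=include_target))
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_huge_h_reduces_to_plain_average(self, small_recons):
        out = mrnlm_filter(small_recons, MRNLMParams(h=1e12, include_target=True))
        avg = mr_average(small_recons, include_target=True)
        np.testing.assert_allclose(out.data, avg.data, rtol=1e-6)

    def test_single_voxel_hand_computation(self):
        """One voxel, target 1.0 (self weight 1), auxiliaries 0.8 and 0.4:
        the output is the hand-evaluated normalised weighted mean with
        weights exp(-(f_t - f_aux)^2 / h^2); h is chosen so the 0.4
        auxiliary carries weight exactly 1/2."""
        h = math.sqrt((1.0 - 0.4) ** 2 / math.log(2.0))
        target = Volume(np.full((1, 1, 1), 1.0))
        aux_a = Volume(np.full((1, 1, 1), 0.8))
        aux_b = Volume(np.full((1, 1, 1), 0.4))
        recons = MultiReconSet(target, (aux_a, aux_b))
        params = MRNLMParams(h=h, patch=PatchSpec((0, 0, 0)), include_target=True)
        out = mrnlm_filter(recons, params)
        w_a = math.exp(-((1.0 - 0.8) ** 2) / h**2)
        w_b = 0.5
        expected = (1.0 + w_a * 0.8 + w_b * 0.4) / (1.0 + w_a + w_b)
        assert out.data[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_matches_naive_loop(self, small_recons):
        params = MRNLMParams(h=0.35, patch=PatchSpec((2, 2, 0)), include_target=True)
        got = mrnlm_filter(small_recons, params)
        want = naive_mrnlm(small_recons, 0.35, (2, 2, 0), True)
        np.testing.assert_allclose(got.data, want.data, rtol=1e-10)

    def test_permutation_invariance(self, small_recons):
        params = MRNLMParams(h=0.3)
        ref = mrnlm_filter(small_recons, params)
        shuffled = MultiReconSet(
            small_recons.target, small_recons.auxiliaries[::-1], small_recons.labels[::-1]
        )
        out = mrnlm_filter(shuffled, params)
        np.testing.assert_allclose(out.data, ref.data, rtol=1e-10)

    def test_empty_auxiliaries_rejected(self, small_volume):
        with pytest.raises(ParameterError):
            mrnlm_filter(MultiReconSet(small_volume, ()), MRNLMParams())

    def test_noise_variance_reduced(self, rng):
        """Constant scene + independent noise: output variance well below
        the target's (at least 2x margin)."""
        shape = (24, 24, 8)
        make = lambda: Volume(10.0 + 0.5 * rng.standard_normal(shape))
        recons = MultiReconSet(make(), tuple(make() for _ in range(12)))
        out = mrnlm_filter(recons, MRNLMParams(h=2.0))
        assert out.data.var() < recons.target.data.var() / 2.0


class TestMRAverage:
    def test_two_identical_volumes(self, small_volume):
        recons = MultiReconSet(small_volume, (small_volume,))
        out = mr_average(recons, include_target=True)
        np.testing.assert_allclose(out.data, small_volume.data, rtol=1e-15)

    def test_mean_of_target_and_auxiliary(self):
        target = Volume(np.full((4, 4, 2), 2.0))
        aux = Volume(np.full((4, 4, 2), 4.0))
        out = mr_average(MultiReconSet(target, (aux,)), include_target=True)
        np.testing.assert_allclose(out.data, 3.0, rtol=1e-15)

    def test_variance_scales_as_one_over_n(self, rng):
        """Monte-Carlo: averaging N iid noise realisations divides the
        voxelwise variance by ~N."""
        shape = (25, 25, 20)  # 12.5k voxels
        n_images = 8
        vols = [Volume(5.0 + rng.standard_normal(shape)) for _ in range(n_images)]
        recons = MultiReconSet(vols[0], tuple(vols[1:]))
        out = mr_average(recons, include_target=True)
        ratio = out.data.var() / np.mean([v.data.var() for v in vols])
        assert ratio == pytest.approx(1.0 / n_images, rel=0.1)

    def test_empty_set_rejected(self, small_volume):
        with pytest.raises(ParameterError):
            mr_average(MultiReconSet(small_volume, ()))


class TestGaussianFilter:
    def test_zero_fwhm_is_identity(self, small_volume):
        out = gaussian_filter(small_volume, 0.0)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_unit_impulse_kernel_normalised(self):
        data = np.zeros((41, 41, 21))
        data[20, 20, 10] = 1.0
        out = gaussian_filter(Volume(data, (2, 2, 3)), fwhm_mm=6.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_volume_interior_exact(self):
        vol = Volume(np.full((12, 12, 6), 2.5), (2, 2, 3))
        out = gaussian_filter(vol, fwhm_mm=5.0)
        np.testing.assert_allclose(out.data, 2.5, rtol=1e-12)

    def test_anisotropic_sigma_in_voxels(self):
        """FWHM in mm maps to per-axis sigma divided by the voxel size."""
        data = np.zeros((31, 31, 31))
        data[15, 15, 15] = 1.0
        out = gaussian_filter(Volume(data, (1.0, 1.0, 2.0)), fwhm_mm=4.0)
        # the z profile must be twice as narrow (in voxels) as the x profile
        x_profile = out.data[:, 15, 15]
        z_profile = out.data[15, 15, :]
        x_sd = np.sqrt(np.sum(x_profile * (np.arange(31) - 15.0) ** 2) / x_profile.sum())
        z_sd = np.sqrt(np.sum(z_profile * (np.arange(31) - 15.0) ** 2) / z_profile.sum())
        assert x_sd == pytest.approx(2 * z_sd, rel=1e-3)

    def test_negative_fwhm_rejected(self, small_volume):
        with pytest.raises(ParameterError):
            gaussian_filter(small_volume, -1.0)


class TestBilateralFilter:
    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((7, 7, 3), 1.7))
        out = bilateral_filter(vol, BilateralParams(sigma_spatial=1.0, sigma_intensity=0.2))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_matches_naive_loop(self, small_volume):
        params = BilateralParams(sigma_spatial=1.2, sigma_intensity=0.3)
        got = bilateral_filter(small_volume, params)
        want = naive_bilateral(small_volume, 1.2, 0.3)
        np.testing.assert_allclose(got.data, want.data, rtol=1e-10)

    def test_infinite_intensity_sigma_is_spatial_gaussian(self, small_volume):
        """sigma_In -> inf: the intensity kernel flattens to 1 and only the
        spatial Gaussian weighting over the same neighbourhood remains."""
        got = bilateral_filter(
            small_volume, BilateralParams(sigma_spatial=1.0, sigma_intensity=1e12)
        )
        data = small_volume.data
        shape = data.shape
        num = np.zeros(shape)
        den = np.zeros(shape)
        r = 3
        for d in itertools.product(range(-r, r + 1), repeat=3):
            d2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2
            if d2 > 9:
                continue
            w = math.exp(-d2 / 2.0)
            vsl = tuple(slice(max(0, -dd), n - max(0, dd)) for dd, n in zip(d, shape))
            csl = tuple(slice(s.start + dd, s.stop + dd) for s, dd in zip(vsl, d))
            num[vsl] += w * data[csl]
            den[vsl] += w
        np.testing.assert_allclose(got.data, num / den, rtol=1e-6)

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ParameterError):
            BilateralParams(sigma_spatial=0.0, sigma_intensity=0.3)
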