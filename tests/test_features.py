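"""Moments, orientation estimation and the rotation-invariant filter bank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import analytic_ridge
from vitreoseg.features import (
    FilterBank,
    ImagePatch,
    circular_mask,
    compute_moments,
    extract_features,
    learn_filter_bank,
    orientation_map,
    patch_orientation,
    raw_moment,
    rotate_patch,
    rotated_kernel_bank,
)
from vitreoseg.types import OCTVolume


def direct_moment(pixels, mask, p, q, masked=True):
    """Brute-force double-loop oracle for the masked image moments."""
    total = 0.0
    for y in range(pixels.shape[0]):
        for x in range(pixels.shape[1]):
            w = pixels[y, x]
            if masked:
                w *= mask[y, x]
            total += (x**p) * (y**q) * w
    return total


def angular_error_deg(a, b):
    """Smallest difference between two axial angles (mod 180°), degrees."""
    return abs((np.rad2deg(a - b) + 90.0) % 180.0 - 90.0)


class TestMoments:
    def test_all_ones_unmasked_m00_counts_pixels(self):
        patch = ImagePatch(np.ones((21, 21)))
        assert raw_moment(patch, 0, 0, masked=False) == 441

    def test_all_ones_masked_m00_counts_disc_pixels(self):
        patch = ImagePatch(np.ones((21, 21)))
        disc = sum(
            1
            for y in range(21)
            for x in range(21)
            if (x - 10) ** 2 + (y - 10) ** 2 <= 10.5**2
        )
        assert raw_moment(patch, 0, 0, masked=True) == disc

    def test_single_pixel_first_moment(self):
        pix = np.zeros((21, 21))
        pix[7, 3] = 1.0  # (x=3, y=7)
        patch = ImagePatch(pix)
        assert raw_moment(patch, 1, 0, masked=False) == 3
        assert raw_moment(patch, 0, 1, masked=False) == 7

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            raw_moment(ImagePatch(np.ones((21, 21))), -1, 0)

    def test_empty_mask_is_degenerate(self):
        with pytest.raises(ValueError, match="empty mask"):
            raw_moment(ImagePatch(np.ones((5, 5)), np.zeros((5, 5), bool)), 0, 0)

    @given(
        arrays(
            np.float64,
            (21, 21),
            elements=st.floats(0.0, 10.0, allow_nan=False),
        )
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_raw_moment_matches_oracle_for_any_patch(self, pix):
        patch = ImagePatch(pix)
        mask = patch.mask
        for p, q in [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1)]:
            val = raw_moment(patch, p, q, masked=True)
            ref = direct_moment(pix, mask, p, q)
            assert abs(val - ref) <= 1e-10 * max(1.0, abs(ref))

    def test_moments_match_direct_summation_oracle(self, rng):
        mask = circular_mask()
        for _ in range(20):
            pix = rng.normal(size=(21, 21)) ** 2  # non-negative mass
            patch = ImagePatch(pix)
            ms = compute_moments(patch)
            m00 = direct_moment(pix, mask, 0, 0)
            xbar = direct_moment(pix, mask, 1, 0) / m00
            ybar = direct_moment(pix, mask, 0, 1) / m00
            assert abs(ms.raw[(0, 0)] - m00) < 1e-10 * max(1, abs(m00))
            assert abs(ms.centroid[0] - xbar) < 1e-10
            assert abs(ms.centroid[1] - ybar) < 1e-10
            mu20 = sum(
                (x - xbar) ** 2 * pix[y, x] * mask[y, x]
                for y in range(21)
                for x in range(21)
            ) / m00
            assert abs(ms.central_normalized[0] - mu20) < 1e-9
            assert np.allclose(ms.covariance, ms.covariance.T)


class TestOrientation:
    def test_horizontal_ridge_is_zero(self):
        phi = patch_orientation(ImagePatch(analytic_ridge(0.0)))
        assert abs(phi) < 1e-6

    @pytest.mark.parametrize("theta_deg", range(0, 180, 15))
    def test_analytic_ridge_angle_recovered(self, theta_deg):
        theta = np.deg2rad(theta_deg)
        phi = patch_orientation(ImagePatch(analytic_ridge(theta)))
        assert angular_error_deg(phi, theta) <= 3.0

    def test_uniform_patch_degenerate_zero(self):
        phi, degenerate = patch_orientation(
            ImagePatch(np.full((21, 21), 2.5)), return_degenerate=True
        )
        assert phi == 0.0 and degenerate

    @pytest.mark.parametrize("dtheta_deg", [10, 30, 55, 80])
    def test_rotation_equivariance(self, dtheta_deg):
        base = analytic_ridge(np.deg2rad(20))
        dtheta = np.deg2rad(dtheta_deg)
        phi0 = patch_orientation(ImagePatch(base))
        phi1 = patch_orientation(ImagePatch(rotate_patch(base, dtheta)))
        assert angular_error_deg(phi1, phi0 + dtheta) <= 3.0


class TestOrientationMap:
    def test_matches_per_patch_oracle(self, small_phantoms, rng):
        img = small_phantoms["shallow_vma"][0].data[3].astype(float)
        omap = orientation_map(img)
        for _ in range(8):
            r = int(rng.integers(10, img.shape[0] - 10))
            c = int(rng.integers(10, img.shape[1] - 10))
            phi = patch_orientation(ImagePatch(img[r - 10 : r + 11, c - 10 : c + 11]))
            assert abs(phi - omap.angles[r, c]) < 1e-10

    def test_horizontal_stripes_map_to_zero(self):
        img = np.tile(np.sin(np.arange(64) / 3.0)[:, None], (1, 64))
        omap = orientation_map(img)
        interior = omap.angles[15:-15, 15:-15]
        # stripes vary along rows -> structure runs along x -> angle 0
        assert np.max(np.abs(interior)) < np.deg2rad(3)

    def test_diagonal_structure_recovered(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        img = np.sin((xx + yy) / 4.0)  # stripes along the -45°/135° diagonal
        omap = orientation_map(img)
        interior = omap.angles[20:-20, 20:-20][~omap.degenerate[20:-20, 20:-20]]
        errs = np.abs((np.rad2deg(interior) + 45.0 + 90.0) % 180.0 - 90.0)
        assert np.median(errs) < 5.0

    def test_constant_image_fully_degenerate(self):
        omap = orientation_map(np.ones((32, 32)))
        assert omap.degenerate.all()
        assert np.all(omap.angles == 0.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            orientation_map(np.ones((10, 10)))


class TestFilterBank:
    def test_explained_variance_nonincreasing(self, small_bank):
        ev = small_bank.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_kernels_orthonormal_in_mask(self, small_bank):
        K = small_bank.kernels.reshape(small_bank.n_kernels, -1)
        gram = K @ K.T
        assert np.abs(gram - np.eye(small_bank.n_kernels)).max() < 1e-8
        # support confined to the disc
        assert np.all(small_bank.kernels[:, ~small_bank.mask] == 0)

    def test_rank_error_for_too_few_patches(self, small_phantoms):
        img = small_phantoms["attached"][0].data[0]
        with pytest.raises(ValueError, match="rank"):
            learn_filter_bank([img], n_patches=10)

    def test_identical_patches_yield_zero_variance_tail(self):
        img = np.tile(np.sin(np.arange(64) / 2.0)[None, :], (64, 1))
        bank = learn_filter_bank([img], n_patches=50, seed=0)
        # one repeated structure: almost all variance in the leading components
        assert bank.explained_variance[5:].sum() < 0.05

    def test_deterministic_for_fixed_seed(self, small_phantoms):
        imgs = [small_phantoms["attached"][0].data[b] for b in range(3)]
        b1 = learn_filter_bank(imgs, n_patches=300, seed=5)
        b2 = learn_filter_bank(imgs, n_patches=300, seed=5)
        assert np.array_equal(b1.kernels, b2.kernels)

    def test_ridge_training_yields_ridge_like_first_kernel(self, rng):
        # images with isolated ridges (spacing > patch size) at random angles
        imgs = []
        for i in range(6):
            yy, xx = np.mgrid[0:120, 0:120].astype(float)
            theta = rng.uniform(0, np.pi)
            d = -(xx - 60) * np.sin(theta) + (yy - 60) * np.cos(theta)
            imgs.append(np.exp(-(((d + 20) % 40 - 20) ** 2) / 4.0))
        bank = learn_filter_bank(imgs, n_patches=800, seed=1)
        template = analytic_ridge(0.0, sigma=np.sqrt(2.0)) * bank.mask
        template -= template[bank.mask].mean()
        k0 = bank.kernels[0]
        r = np.corrcoef(template[bank.mask], k0[bank.mask])[0, 1]
        assert abs(r) > 0.8


class TestExtractFeatures:
    def test_constant_volume_constant_response(self, small_bank):
        vol = OCTVolume(np.full((2, 32, 48), 2.0, np.float32), (3.87, 120, 370))
        fs = extract_features(vol, small_bank, n_orientation_bins=24)
        # constant image: orientation degenerate (angle 0) everywhere, so one
        # rotated-kernel set applies; response = c * kernel sum - mean offset
        _, rot = rotated_kernel_bank(small_bank, 24)
        bin0 = int(np.floor((0.0 + np.pi / 2) / np.pi * 24))
        ksum = rot[bin0].sum(axis=(1, 2))
        expect = 2.0 * ksum - small_bank.kernel_offsets()
        assert np.allclose(fs.values, expect[None, None, None, :], atol=1e-4)
        # every voxel carries the same vector
        assert np.abs(fs.values - fs.values[0, 0, 0]).max() < 1e-4

    def test_shape_and_names(self, small_phantoms, small_bank):
        vol = small_phantoms["attached"][0]
        fs = extract_features(vol, small_bank)
        assert fs.values.shape == vol.data.shape + (20,)
        assert fs.names == [f"eig{j:02d}" for j in range(20)]
        assert np.isfinite(fs.values).all()

    def test_response_equals_rotated_kernel_dot_product(self, small_phantoms, small_bank, rng):
        """Direct per-pixel oracle: response = patch . (kernel rotated by the
        pixel's quantized orientation), minus the training-mean offset."""
        vol = small_phantoms["shallow_vma"][0]
        fs = extract_features(vol, small_bank, n_orientation_bins=24)
        b = 2
        img = vol.data[b].astype(float)
        omap = orientation_map(img)
        bins = np.clip(
            np.floor((omap.angles + np.pi / 2) / np.pi * 24).astype(int), 0, 23
        )
        _, rot = rotated_kernel_bank(small_bank, 24)
        offsets = small_bank.kernel_offsets()
        pad = np.pad(img, 10, mode="symmetric")
        for _ in range(10):
            r = int(rng.integers(0, img.shape[0]))
            c = int(rng.integers(0, img.shape[1]))
            win = pad[r : r + 21, c : c + 21]
            expect = np.array(
                [np.sum(win * rot[bins[r, c], j]) for j in range(20)]
            ) - offsets
            scale = max(1.0, np.abs(expect).max())
            assert np.abs(fs.values[b, r, c] - expect).max() / scale < 1e-5

    def test_eigenfeature_rotation_invariance(self, small_bank):
        """Responses to a ridge and its 40°-rotated copy differ by <10%."""
        mask = small_bank.mask
        K = small_bank.kernels.reshape(20, -1)

        def response(patch):
            phi = patch_orientation(ImagePatch(patch, mask))
            canon = rotate_patch(patch, -phi) * mask
            vec = (canon - small_bank.mean_patch * mask).reshape(-1)
            return K @ vec

        r0 = response(analytic_ridge(0.0))
        r40 = response(analytic_ridge(np.deg2rad(40.0)))
        rel = np.linalg.norm(r0 - r40) / max(np.linalg.norm(r0), np.linalg.norm(r40))
        assert rel < 0.10
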