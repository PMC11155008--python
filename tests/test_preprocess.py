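"""Resampling, centering, patch extraction and augmentation."""

import numpy as np
import pytest

from fedcrt.preprocess import (
    AugmentationConfig,
    Patch,
    augment,
    extract_patch,
    normalize_intensity,
    resample_isotropic,
    tumor_center,
)
from fedcrt.volumes import BinaryMask, ImageVolume


def sphere_mask(shape, center, radius_mm, spacing):
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing[0],
        (np.arange(shape[1]) + 0.5) * spacing[1],
        (np.arange(shape[2]) + 0.5) * spacing[2],
        indexing="ij",
    )
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return BinaryMask(data=(d2 <= radius_mm ** 2).astype(np.uint8), spacing=spacing)


class TestResample:
    def test_constant_volume_preserved_and_shape_doubled(self):
        vol = ImageVolume(np.full((10, 12, 14), 7.0), spacing=(2, 2, 2))
        out = resample_isotropic(vol, (1, 1, 1))
        assert out.shape == (20, 24, 28)
        assert out.spacing == (1.0, 1.0, 1.0)
        interior = out.data[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, 7.0, atol=1e-9)

    def test_identity_resample_is_near_exact(self, rng):
        vol = ImageVolume(rng.random((8, 9, 10)), spacing=(1, 1, 1))
        out = resample_isotropic(vol, (1, 1, 1))
        assert out.shape == vol.shape
        assert np.abs(out.data - vol.data).max() < 1e-6

    def test_sphere_mask_volume_conserved(self):
        mask = sphere_mask((40, 80, 80), (40, 40, 40), 10.0, (2.0, 1.0, 1.0))
        out = resample_isotropic(mask, (1, 1, 1), mode="nearest")
        expected = 4.0 / 3.0 * np.pi * 1000.0
        assert out.voxel_count() == pytest.approx(expected, rel=0.05)
        assert set(np.unique(out.data)) <= {0, 1}

    @pytest.mark.parametrize("semi_axis", [5.0, 8.0, 12.0])
    def test_ellipsoid_volume_conservation_across_sizes(self, semi_axis):
        """Mask volume in mm^3 is preserved within 5% for semi-axes >= 5 mm."""
        mask = sphere_mask((60, 60, 120), (45, 30, 30), semi_axis, (1.5, 1.0, 0.5))
        out = resample_isotropic(mask, (1, 1, 1), mode="nearest")
        assert out.volume_mm3() == pytest.approx(mask.volume_mm3(), rel=0.05)

    def test_mask_requires_nearest(self):
        mask = sphere_mask((10, 10, 10), (5, 5, 5), 3.0, (1, 1, 1))
        with pytest.raises(ValueError, match="nearest"):
            resample_isotropic(mask, (0.5, 0.5, 0.5), mode="bspline")

    def test_degenerate_axis_fails(self):
        vol = ImageVolume(np.zeros((2, 10, 10)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="zero extent"):
            resample_isotropic(vol, (5.0, 1.0, 1.0))


class TestTumorCenter:
    def test_single_voxel(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[5, 6, 7] = 1
        assert tumor_center(BinaryMask(data, (1, 1, 1))) == (5, 6, 7)

    def test_two_voxel_midpoint_rounds_half_up(self):
        data = np.zeros((4, 4, 4), dtype=np.uint8)
        data[0, 0, 0] = 1
        data[2, 0, 0] = 1
        assert tumor_center(BinaryMask(data, (1, 1, 1))) == (1, 0, 0)

    def test_matches_brute_force_mean(self, rng):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        idx = rng.choice(20 ** 3, size=50, replace=False)
        data.ravel()[idx] = 1
        got = tumor_center(BinaryMask(data, (1, 1, 1)))
        coords = np.argwhere(data)
        expected = tuple(int(np.floor(coords[:, ax].mean() + 0.5)) for ax in range(3))
        assert got == expected

    def test_empty_mask_fails(self):
        with pytest.raises(ValueError, match="empty"):
            tumor_center(BinaryMask(np.zeros((5, 5, 5), dtype=np.uint8), (1, 1, 1)))


class TestExtractPatch:
    def test_constant_volume_gives_constant_patch(self):
        vol = ImageVolume(np.full((80, 80, 80), 100.0), spacing=(1, 1, 1))
        p = extract_patch(vol, (40, 40, 40), size=64, window=(0.0, 200.0))
        assert p.data.shape == (64, 64, 64)
        assert np.allclose(p.data, 0.5)

    def test_corner_center_pads_all_but_one_octant(self):
        vol = ImageVolume(np.full((80, 80, 80), 200.0), spacing=(1, 1, 1))
        p = extract_patch(vol, (0, 0, 0), size=64, window=(0.0, 200.0), pad_value=0.0)
        assert np.all(p.data[32:, 32:, 32:] == 1.0)  # in-volume octant
        assert np.all(p.data[:32, :, :] == 0.0)  # padded region
        assert np.all(p.data[:, :32, :] == 0.0)
        assert np.all(p.data[:, :, :32] == 0.0)

    def test_mask_count_conserved_inside_patch(self):
        mask = sphere_mask((80, 80, 80), (40, 40, 40), 10.0, (1, 1, 1))
        center = tumor_center(mask)
        vol = ImageVolume(mask.data.astype(float), spacing=(1, 1, 1))
        p = extract_patch(vol, center, size=64, window=(0.0, 1.0))
        assert int(p.data.sum()) == mask.voxel_count()

    @pytest.mark.parametrize("center", [(0, 0, 0), (79, 79, 79), (40, 0, 79), (40, 40, 40)])
    def test_patch_shape_invariant_to_center_position(self, center):
        vol = ImageVolume(np.ones((80, 80, 80)), spacing=(1, 1, 1))
        p = extract_patch(vol, center, size=64, window=(0, 1))
        assert p.data.shape == (64, 64, 64)
        assert p.data.min() >= 0.0 and p.data.max() <= 1.0

    def test_center_outside_volume_fails(self):
        vol = ImageVolume(np.ones((40, 40, 40)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            extract_patch(vol, (200, 20, 20), size=64)

    def test_window_clipping(self):
        data = np.array([[[-2000.0, -1000.0, 0.0, 400.0, 1000.0]]])
        out = normalize_intensity(data, window=(-1000, 400))
        assert np.allclose(out.ravel(), [0.0, 0.0, 1000 / 1400, 1.0, 1.0])


def spherical_patch(size=32):
    """Radially symmetric cone profile, zero outside the inscribed sphere so
    rotation about any central axis is (up to interpolation) the identity."""
    zz, yy, xx = np.indices((size, size, size))
    c = (size - 1) / 2
    r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
    return Patch(np.clip(1.0 - r / (size / 2), 0.0, 1.0))


class TestAugment:
    def test_disabled_config_is_identity(self, rng):
        p = Patch(rng.random((16, 16, 16)))
        out = augment(p, AugmentationConfig(enabled=False), seed=5)
        assert out.data is p.data

    def test_forced_flip_is_an_involution(self, rng):
        cfg = AugmentationConfig(
            flip_prob=1.0, rotation_range_deg=(0, 0), crop_pad_voxels=0,
            brightness=0.0, contrast=0.0,
        )
        p = Patch(rng.random((16, 16, 16)))
        twice = augment(augment(p, cfg, seed=1), cfg, seed=2)
        assert np.allclose(twice.data, p.data)

    def test_rotation_preserves_spherical_symmetry(self):
        cfg = AugmentationConfig(
            flip_prob=0.0, crop_pad_voxels=0, brightness=0.0, contrast=0.0
        )
        p = spherical_patch()
        out = augment(p, cfg, seed=3)
        assert np.abs(out.data - p.data).mean() < 0.02  # 2% of dynamic range

    @pytest.mark.parametrize("seed", [0, 1, 17, 99])
    def test_output_range_shape_label_preserved(self, seed, rng):
        p = Patch(rng.random((16, 16, 16)), patient_id="p1", label=1)
        out = augment(p, AugmentationConfig(), seed=seed)
        assert out.data.shape == p.data.shape
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0
        assert out.label == 1 and out.patient_id == "p1"

    def test_deterministic_given_seed(self, rng):
        p = Patch(rng.random((16, 16, 16)))
        a = augment(p, AugmentationConfig(), seed=7)
        b = augment(p, AugmentationConfig(), seed=7)
        assert np.array_equal(a.data, b.data)
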