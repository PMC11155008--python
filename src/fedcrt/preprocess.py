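"""Tumor-patch preprocessing: isotropic resampling, centering, extraction, augmentation.

The model consumes a fixed-size cube cut from the CT around the tumor
centroid.  Volumes are first resampled to isotropic 1 mm voxels (cubic
B-spline for images, nearest neighbour for masks, which keeps them binary),
the mask centroid defines the patch centre, and intensities are normalised to
``[0, 1]`` by clipping to a window and rescaling.  Out-of-volume regions are
padded with the normalised minimum (0.0, i.e. "air").

Training-time augmentation follows the usual 2D-style recipe applied to the
axial geometry of a chest CT: random left-right flip, random rotation about
the cranio-caudal (z) axis in [-15, 15] degrees, random crop after constant
padding, and brightness/contrast jitter with factor U(0.8, 1.2).  Saturation
and hue factors are carried in the config for completeness but are inert on
single-channel data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import BinaryMask, ImageVolume, _to_sitk

__all__ = [
    "Patch",
    "AugmentationConfig",
    "resample_isotropic",
    "tumor_center",
    "extract_patch",
    "normalize_intensity",
    "augment",
    "DEFAULT_WINDOW",
]

#: Default clipping window in HU-like units (lung window floor to soft tissue).
DEFAULT_WINDOW = (-1000.0, 400.0)

PATCH_SIZE = 64


@dataclass
class Patch:
    """A normalised cubic tumor patch plus its label and provenance."""

    data: np.ndarray  # (size, size, size), values in [0, 1]
    patient_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"patch must be a cube, got shape {self.data.shape}")
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise ValueError("patch intensities must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.data.shape[0]


@dataclass
class AugmentationConfig:
    """Stochastic augmentation settings (all draws seeded by the caller)."""

    enabled: bool = True
    flip_prob: float = 0.5
    rotation_range_deg: tuple[float, float] = (-15.0, 15.0)
    crop_pad_voxels: int = 4
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2  # inert on single-channel data
    hue: float = 0.2  # inert on single-channel data
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.crop_pad_voxels < 0:
            raise ValueError("crop_pad_voxels must be nonnegative")


_INTERPOLATORS = {"bspline": sitk.sitkBSpline, "nearest": sitk.sitkNearestNeighbor}


def resample_isotropic(
    vol: ImageVolume,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: str = "bspline",
) -> ImageVolume:
    """Resample a volume to the target spacing (default 1 x 1 x 1 mm).

    Images use cubic B-spline interpolation; masks must use ``mode="nearest"``
    so the output stays binary.  The output shape per axis is
    ``round(input_shape * input_spacing / target_spacing)``.
    """
    if mode not in _INTERPOLATORS:
        raise ValueError(f"mode must be one of {sorted(_INTERPOLATORS)}, got {mode!r}")
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    new_shape = tuple(
        int(round(n * s / t)) for n, s, t in zip(vol.data.shape, vol.spacing, target_spacing)
    )
    for ax, n in enumerate(new_shape):
        if n < 1:
            raise ValueError(f"resampling collapses axis {ax} to zero extent")

    img = _to_sitk(ImageVolume(np.asarray(vol.data, dtype=np.float64), vol.spacing, vol.origin))
    out = sitk.Resample(
        img,
        tuple(reversed(new_shape)),  # SimpleITK size is (x, y, z)
        sitk.Transform(),
        _INTERPOLATORS[mode],
        img.GetOrigin(),
        tuple(reversed(target_spacing)),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    data = sitk.GetArrayFromImage(out)
    if isinstance(vol, BinaryMask):
        if mode != "nearest":
            raise ValueError("binary masks must be resampled with mode='nearest'")
        return BinaryMask(data=(data > 0.5).astype(np.uint8), spacing=target_spacing, origin=vol.origin)
    return ImageVolume(data=data, spacing=target_spacing, origin=vol.origin)


def tumor_center(mask: BinaryMask) -> tuple[int, int, int]:
    """Centroid of the nonzero mask voxels, rounded half-up per axis."""
    coords = np.nonzero(mask.data)
    if coords[0].size == 0:
        raise ValueError("cannot locate tumor center: mask is empty")
    return tuple(int(np.floor(c.mean() + 0.5)) for c in coords)


def normalize_intensity(data: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Clip to ``window`` and rescale linearly to [0, 1]."""
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window upper bound must exceed lower bound")
    return np.clip((np.asarray(data, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)


def extract_patch(
    vol: ImageVolume,
    center: tuple[int, int, int],
    size: int = PATCH_SIZE,
    window: tuple[float, float] = DEFAULT_WINDOW,
    pad_value: float = 0.0,
    patient_id: str = "",
    label: int | None = None,
) -> Patch:
    """Cut a ``size``^3 patch centred on ``center`` from a 1 mm-resampled volume.

    The centre voxel lands at index ``size // 2`` on every axis.  Regions
    falling outside the volume are filled with ``pad_value`` (applied after
    normalisation, default 0.0 = the normalised minimum).
    """
    if size < 1:
        raise ValueError("patch size must be positive")
    norm = normalize_intensity(vol.data, window)
    half = size // 2
    out = np.full((size, size, size), float(pad_value), dtype=np.float64)
    starts = [int(c) - half for c in center]
    for ax, (s, n) in enumerate(zip(starts, norm.shape)):
        if s + size <= 0 or s >= n:
            raise ValueError(
                f"patch centered at {tuple(center)} lies entirely outside the volume on axis {ax}"
            )
    src = tuple(slice(max(s, 0), min(s + size, n)) for s, n in zip(starts, norm.shape))
    dst = tuple(slice(sl.start - s, sl.stop - s) for sl, s in zip(src, starts))
    out[dst] = norm[src]
    return Patch(data=out, patient_id=patient_id, label=label)


def patch_from_pair(
    vol: ImageVolume,
    mask: BinaryMask,
    size: int = PATCH_SIZE,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    window: tuple[float, float] = DEFAULT_WINDOW,
    patient_id: str = "",
    label: int | None = None,
) -> Patch:
    """Full pipeline for one patient: resample image+mask, centre, extract."""
    rvol = resample_isotropic(vol, target_spacing, mode="bspline")
    rmask = resample_isotropic(mask, target_spacing, mode="nearest")
    center = tumor_center(rmask)
    return extract_patch(rvol, center, size=size, window=window, patient_id=patient_id, label=label)


def cohort_window(manifest, quantiles: tuple[float, float] = (0.0, 1.0)) -> tuple[float, float]:
    """Intensity window spanning the (min, max) of the listed volumes.

    Streams the images once; used to derive a per-cohort normalisation
    window for phantom data, where the fixed CT window does not apply.
    """
    from .volumes import read_volume  # local import to avoid cycles

    lo, hi = np.inf, -np.inf
    for path in manifest["image_path"]:
        data = read_volume(path).data
        lo = min(lo, np.quantile(data, quantiles[0]))
        hi = max(hi, np.quantile(data, quantiles[1]))
    if not np.isfinite(lo) or hi <= lo:
        raise ValueError("could not derive an intensity window from the cohort")
    return float(lo), float(hi)


def patches_from_manifest(
    manifest,
    size: int = PATCH_SIZE,
    window: tuple[float, float] = DEFAULT_WINDOW,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
):
    """Run the preprocessing pipeline over a manifest.

    Returns ``(X, y, site_ids, patient_ids)`` with ``X`` of shape
    ``(n, size, size, size)`` and ``y`` binary (1 = responsive).
    """
    from .volumes import read_mask, read_volume

    xs, ys = [], []
    for row in manifest.itertuples(index=False):
        vol = read_volume(row.image_path)
        mask = read_mask(row.mask_path)
        patch = patch_from_pair(
            vol, mask, size=size, target_spacing=target_spacing, window=window,
            patient_id=row.patient_id,
        )
        xs.append(patch.data)
        ys.append(1 if str(row.label).lower().startswith("resp") else 0)
    x = np.stack(xs)
    y = np.asarray(ys, dtype=int)
    return x, y, manifest["site_id"].to_numpy(), manifest["patient_id"].to_numpy()


def augment(patch: Patch, cfg: AugmentationConfig, seed: int) -> Patch:
    """Apply the augmentation chain to a patch, deterministically given ``seed``.

    Order: horizontal (x-axis) flip with ``flip_prob``; rotation about z by
    U(-15, 15) degrees with edge fill ``pad_value``; pad-then-random-crop back
    to the original size; brightness then contrast jitter; re-clip to [0, 1].
    The label is never touched.  ``enabled=False`` returns the patch unchanged.
    """
    if not cfg.enabled:
        return patch
    rng = np.random.default_rng(seed)
    data = patch.data

    if rng.random() < cfg.flip_prob:
        data = np.flip(data, axis=2)

    lo, hi = cfg.rotation_range_deg
    angle = rng.uniform(lo, hi)
    data = ndimage.rotate(
        data, angle, axes=(1, 2), reshape=False, order=1, mode="constant", cval=cfg.pad_value
    )

    c = cfg.crop_pad_voxels
    if c > 0:
        size = patch.size
        padded = np.pad(data, c, mode="constant", constant_values=cfg.pad_value)
        offs = rng.integers(0, 2 * c + 1, size=3)
        data = padded[
            offs[0] : offs[0] + size, offs[1] : offs[1] + size, offs[2] : offs[2] + size
        ]

    if cfg.brightness > 0:
        data = data * rng.uniform(1.0 - cfg.brightness, 1.0 + cfg.brightness)
    if cfg.contrast > 0:
        m = data.mean()
        data = m + (data - m) * rng.uniform(1.0 - cfg.contrast, 1.0 + cfg.contrast)

    return Patch(data=np.clip(data, 0.0, 1.0), patient_id=patch.patient_id, label=patch.label)
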