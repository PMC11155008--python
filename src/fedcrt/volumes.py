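"""3D image volumes and binary masks with physical voxel spacing.

Arrays are indexed ``(z, y, x)`` with 0-based voxel indices; ``spacing`` and
``origin`` are given in millimetres per axis in the same ``(z, y, x)`` order.
NIfTI files store geometry in ``(x, y, z)`` order, so the I/O helpers reverse
the spacing/origin triples at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = ["ImageVolume", "BinaryMask", "read_volume", "read_mask", "write_volume"]


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing and origin in mm.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities (CT numbers for real data, arbitrary units for
        phantoms). Must be finite.
    spacing : tuple of float
        Physical size of a voxel per axis, ``(dz, dy, dx)`` in mm.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Axis extents in mm (shape times spacing)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


@dataclass
class BinaryMask(ImageVolume):
    """A {0,1} mask aligned to an :class:`ImageVolume` (same shape/geometry)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        """Mask volume = voxel count times voxel volume."""
        return self.voxel_count() * float(np.prod(self.spacing))


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    data = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return data, spacing, origin


def write_volume(vol: ImageVolume, path: str) -> None:
    """Write a volume (or mask) to NIfTI with spacing recorded in the header."""
    sitk.WriteImage(_to_sitk(vol), str(path))


def read_volume(path: str) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) image into an :class:`ImageVolume`."""
    data, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return ImageVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def read_mask(path: str) -> BinaryMask:
    """Read a NIfTI mask; values are binarised at 0.5 to guard against rounding."""
    data, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return BinaryMask(data=(np.asarray(data) > 0.5).astype(np.uint8), spacing=spacing, origin=origin)
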