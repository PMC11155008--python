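"""Multi-site synthetic phantom cohorts for the response-prediction pipeline.

Real chemoradiotherapy cohorts are private, so every downstream stage is
exercised on phantoms: ellipsoidal "tumors" embedded in a homogeneous
background, with site-level distribution shift (intensity offset, noise
level, voxel spacing) emulating the non-IID behaviour of multi-hospital CT.

The class signal is morphological: responsive and nonresponsive patients
draw their tumor semi-axes from different means, with the separation scaled
by ``label_effect_size`` (0 = identical classes, 1 = the configured means)
and degraded by ``label_noise`` (probability that a patient's morphology is
drawn from the opposite class).  Labels themselves are assigned per site,
by default in exact-count mode so per-site class counts are deterministic.

Seed discipline: the cohort is a pure function of (specs, master seed).
Patient ``i`` of site ``j`` derives its seed from
``SeedSequence([master_seed, j, i])``, so adding sites or patients never
changes previously generated patients.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryMask, ImageVolume, write_volume

__all__ = [
    "SiteSpec",
    "PhantomSpec",
    "make_phantom",
    "generate_cohort",
    "load_manifest",
    "equivalent_radius_mm",
    "default_sites",
    "default_phantom",
    "desk_scale_sites",
    "desk_scale_test_site",
    "desk_scale_phantom",
]

MANIFEST_COLUMNS = ["patient_id", "site_id", "label", "age", "sex", "image_path", "mask_path"]

#: Labels are stored as strings in the manifest; 1 = responsive throughout.
LABEL_NAMES = {1: "responsive", 0: "nonresponsive"}


@dataclass
class SiteSpec:
    """One hospital-like site: cohort size, prevalence, and distribution shift."""

    site_id: str
    n_patients: int
    responsive_fraction: float
    intensity_offset: float = 0.0
    noise_sd: float = 8.0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    age_mean: float = 65.0
    age_sd: float = 9.0
    male_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("each site needs at least 2 patients")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(not 0.5 <= s <= 5.0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing components must lie in [0.5, 5.0] mm, got {self.voxel_spacing}")


@dataclass
class PhantomSpec:
    """Geometry and intensity model of the synthetic tumor volumes."""

    volume_shape: tuple[int, int, int] = (48, 96, 96)
    tumor_axes_mean_responsive: tuple[float, float, float] = (7.0, 7.0, 7.0)
    tumor_axes_mean_nonresponsive: tuple[float, float, float] = (11.0, 11.0, 11.0)
    tumor_axes_sd: float = 1.5
    tumor_intensity_contrast: float = 60.0
    texture_sd: float = 10.0
    label_effect_size: float = 1.0
    label_noise: float = 0.15
    background: float = 0.0
    center_jitter_mm: float = 5.0
    patch_extent_mm: float = 64.0
    min_axis_mm: float = 1.2

    def __post_init__(self) -> None:
        for name in ("tumor_axes_mean_responsive", "tumor_axes_mean_nonresponsive"):
            axes = tuple(float(a) for a in getattr(self, name))
            if any(a <= 1.0 for a in axes):
                raise ValueError(f"{name}: all semi-axes must exceed 1 mm")
            if any(2 * a > self.patch_extent_mm for a in axes):
                raise ValueError(
                    f"{name}: tumor extent must fit the {self.patch_extent_mm:g} mm patch"
                )
            setattr(self, name, axes)
        if self.tumor_axes_sd <= 0:
            raise ValueError("tumor_axes_sd must be positive")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must be in [0, 0.5]")
        if self.label_effect_size < 0:
            raise ValueError("label_effect_size must be nonnegative")

    def class_axes_mean(self, label: int) -> np.ndarray:
        """Effective semi-axis means for a class, scaled by the effect size.

        The two class means are pulled toward their midpoint as
        ``label_effect_size`` shrinks to 0, leaving the classes identical.
        """
        resp = np.asarray(self.tumor_axes_mean_responsive)
        nonr = np.asarray(self.tumor_axes_mean_nonresponsive)
        mid = (resp + nonr) / 2.0
        target = resp if label == 1 else nonr
        return mid + self.label_effect_size * (target - mid)


def _smoothed_texture(rng: np.random.Generator, shape, spacing, sd: float) -> np.ndarray:
    """Spatially correlated intensity texture with empirical SD ``sd``."""
    sigma_vox = [3.0 / s for s in spacing]  # 3 mm correlation length
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    std = tex.std()
    if std > 0:
        tex = tex * (sd / std)
    return tex


def make_phantom(
    phantom: PhantomSpec, site: SiteSpec, label: int, seed: int
) -> tuple[ImageVolume, BinaryMask]:
    """Generate one patient's (image, mask) pair.

    The mask is a single ellipsoid near the volume centre; the image is
    background + site intensity offset + tumor contrast inside the mask +
    smoothed Gaussian texture + white site noise.  Identical
    ``(phantom, site, label, seed)`` give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in phantom.volume_shape)
    spacing = site.voxel_spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])  # mm

    mean_axes = phantom.class_axes_mean(int(label))
    axes = rng.normal(mean_axes, phantom.tumor_axes_sd)
    axes = np.clip(axes, phantom.min_axis_mm, phantom.patch_extent_mm / 2.0)

    for ax in range(3):
        if 2 * axes[ax] >= extent[ax]:
            raise ValueError(
                f"tumor extent {2 * axes[ax]:.1f} mm exceeds volume extent "
                f"{extent[ax]:.1f} mm on axis {ax}"
            )

    center_mm = extent / 2.0
    if phantom.center_jitter_mm > 0:
        lo = axes + np.asarray(spacing)  # one-voxel margin
        hi = extent - axes - np.asarray(spacing)
        jitter = rng.uniform(-phantom.center_jitter_mm, phantom.center_jitter_mm, size=3)
        center_mm = np.clip(center_mm + jitter, lo, np.maximum(lo, hi))

    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing[0],
        (np.arange(shape[1]) + 0.5) * spacing[1],
        (np.arange(shape[2]) + 0.5) * spacing[2],
        indexing="ij",
    )
    q = (
        ((zz - center_mm[0]) / axes[0]) ** 2
        + ((yy - center_mm[1]) / axes[1]) ** 2
        + ((xx - center_mm[2]) / axes[2]) ** 2
    )
    mask_data = (q <= 1.0).astype(np.uint8)

    img = np.full(shape, phantom.background + site.intensity_offset, dtype=np.float64)
    img += phantom.tumor_intensity_contrast * mask_data
    if phantom.texture_sd > 0:
        img += _smoothed_texture(rng, shape, spacing, phantom.texture_sd)
    if site.noise_sd > 0:
        img += rng.normal(0.0, site.noise_sd, size=shape)

    vol = ImageVolume(data=img, spacing=spacing)
    mask = BinaryMask(data=mask_data, spacing=spacing)
    return vol, mask


def equivalent_radius_mm(mask: BinaryMask) -> float:
    """Radius of the sphere with the mask's volume — the morphological feature
    that carries the class signal (mean semi-axis up to shape anisotropy)."""
    v = mask.volume_mm3()
    return float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))


def _patient_seed(master_seed: int, site_index: int, patient_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(site_index), int(patient_index)])
    return int(ss.generate_state(1)[0])


def _site_labels(site: SiteSpec, rng: np.random.Generator, mode: str) -> np.ndarray:
    n = site.n_patients
    if mode == "exact":
        n_resp = int(round(n * site.responsive_fraction))
        labels = np.zeros(n, dtype=int)
        labels[:n_resp] = 1
        rng.shuffle(labels)
    elif mode == "bernoulli":
        labels = (rng.random(n) < site.responsive_fraction).astype(int)
    else:
        raise ValueError("label mode must be 'exact' or 'bernoulli'")
    return labels


def generate_cohort(
    sites: list[SiteSpec],
    phantom: PhantomSpec,
    seed: int,
    out_dir: str | os.PathLike,
    label_mode: str = "exact",
    write_images: bool = True,
) -> pd.DataFrame:
    """Generate a full multi-site cohort and write it to ``out_dir``.

    Writes one NIfTI image/mask pair per patient plus ``manifest.csv`` with
    columns ``patient_id, site_id, label, age, sex, image_path, mask_path``.
    Returns the manifest as a DataFrame (paths absolute).
    """
    if not sites:
        raise ValueError("at least one site is required")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    rows = []
    for j, site in enumerate(sites):
        site_rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(j)]))
        labels = _site_labels(site, site_rng, label_mode)
        for i in range(site.n_patients):
            pseed = _patient_seed(seed, j, i)
            prng = np.random.default_rng(pseed)
            label = int(labels[i])
            # label_noise: morphology drawn from the opposite class, label kept
            morph_label = label
            if phantom.label_noise > 0 and prng.random() < phantom.label_noise:
                morph_label = 1 - label
            vol, mask = make_phantom(phantom, site, morph_label, seed=pseed)

            age = float(np.clip(prng.normal(site.age_mean, site.age_sd), 30.0, 95.0))
            sex = "M" if prng.random() < site.male_fraction else "F"
            pid = f"{site.site_id}-{i:04d}"
            image_path = os.path.join(out_dir, f"{pid}_image.nii.gz")
            mask_path = os.path.join(out_dir, f"{pid}_mask.nii.gz")
            if write_images:
                write_volume(vol, image_path)
                write_volume(mask, mask_path)
            rows.append(
                {
                    "patient_id": pid,
                    "site_id": site.site_id,
                    "label": LABEL_NAMES[label],
                    "age": round(age, 1),
                    "sex": sex,
                    "image_path": image_path,
                    "mask_path": mask_path,
                }
            )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest["patient_id"].duplicated().any():
        raise RuntimeError("duplicate patient ids generated")
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def default_sites() -> list[SiteSpec]:
    """Four hospital-like sites with the reference cohort's sizes and
    per-site responsive prevalence (102/42/32/69 patients, 110/245 responsive
    overall); the fourth site carries the distribution shift (intensity
    offset, heavier noise, coarser spacing)."""
    return [
        SiteSpec("A", 102, 51 / 102, 0.0, 8.0, (2.5, 0.98, 0.98), 64.3, 7.8, 0.80),
        SiteSpec("B", 42, 31 / 42, 0.0, 8.0, (2.5, 1.02, 1.02), 64.2, 10.7, 0.81),
        SiteSpec("C", 32, 17 / 32, 0.0, 8.0, (3.0, 1.00, 1.00), 64.0, 8.6, 0.72),
        SiteSpec("D", 69, 11 / 69, 40.0, 14.0, (3.0, 1.17, 1.17), 68.7, 11.4, 0.52),
    ]


def default_phantom() -> PhantomSpec:
    return PhantomSpec()


def desk_scale_sites(n: tuple[int, int, int] = (60, 30, 30)) -> list[SiteSpec]:
    """Three small sites with moderate shift, for desk-scale experiments."""
    return [
        SiteSpec("S1", n[0], 0.5, 0.0, 5.0, (1.0, 1.0, 1.0)),
        SiteSpec("S2", n[1], 0.5, 10.0, 5.0, (1.0, 1.0, 1.0)),
        SiteSpec("S3", n[2], 0.5, 20.0, 8.0, (1.25, 1.0, 1.0)),
    ]


def desk_scale_test_site(n: int = 40) -> SiteSpec:
    """Held-out external-validation site for desk-scale experiments."""
    return SiteSpec("T", n, 0.5, 5.0, 5.0, (1.0, 1.0, 1.0))


def desk_scale_phantom() -> PhantomSpec:
    """Small volumes with a strong morphological effect; tumors fit a 16 mm patch."""
    return PhantomSpec(
        volume_shape=(32, 48, 48),
        tumor_axes_mean_responsive=(3.5, 3.5, 3.5),
        tumor_axes_mean_nonresponsive=(6.0, 6.0, 6.0),
        tumor_axes_sd=0.6,
        tumor_intensity_contrast=80.0,
        texture_sd=6.0,
        label_effect_size=1.0,
        label_noise=0.0,
        center_jitter_mm=2.0,
        patch_extent_mm=16.0,
    )
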