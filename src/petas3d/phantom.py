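"""Synthetic PET phantom generator with exact gold-standard tumor masks.

Emulates the salient characteristics of clinical FDG-PET for testing the
segmentation pipeline without patient data: an anisotropic voxel grid, a
bright tumor over a dim background, isotropic point-spread blur (world-mm
FWHM), additive noise, and topologically varied tumor shapes (sphere,
ellipsoid, bilobed, torus, two disjoint blobs).

The gold mask is the exact noiseless geometric support of the tumor: a
voxel belongs to the shape iff its *center* lies inside the implicit
surface. Partial-volume effects enter only through the PSF blur of the
intensity image, never the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from petas3d.volume_io import BinaryMask, Grid3D, SUVVolume

__all__ = ["PhantomSpec", "generate_phantom", "roi_around", "SHAPE_KINDS"]

SHAPE_KINDS = ("sphere", "ellipsoid", "bilobed", "torus", "two_blobs")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic PET study.

    Defaults are the study conditions used throughout the test-suite and the
    reproduction script: a desk-scale 64x64x48 grid at the clinical spacing
    2.73 x 2.73 x 3.27 mm, an 8:1 tumor-to-background uptake ratio, additive
    Gaussian noise with sigma = 5% of the tumor uptake, a 4 mm FWHM PSF
    (typical post-reconstruction PET resolution), and a 25 mm tumor radius
    (~65 mL, a clinical-scale biological tumor volume).
    """

    grid: Grid3D = Grid3D((64, 64, 48), (2.73, 2.73, 3.27))
    shape_kind: str = "sphere"
    tumor_uptake: float = 8.0
    background_uptake: float = 1.0
    noise_sigma: float = 0.4
    psf_fwhm_mm: float = 4.0
    seed: int = 0
    radius_mm: float = 25.0
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    poisson_scale: float = 100.0  # pseudo-counts per uptake unit in poisson mode

    def __post_init__(self) -> None:
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}; expected one of {SHAPE_KINDS}")
        if self.tumor_uptake <= self.background_uptake:
            raise ValueError("tumor_uptake must exceed background_uptake")
        if self.noise_sigma < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("noise_sigma and psf_fwhm_mm must be >= 0")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _shape_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean support of the tumor shape via a per-voxel center-inside test."""
    x, y, z = spec.grid.world_coordinates()
    cx = (spec.grid.shape[0] - 1) * spec.grid.spacing[0] / 2.0
    cy = (spec.grid.shape[1] - 1) * spec.grid.spacing[1] / 2.0
    cz = (spec.grid.shape[2] - 1) * spec.grid.spacing[2] / 2.0
    dx, dy, dz = x - cx, y - cy, z - cz
    r = spec.radius_mm

    if spec.shape_kind == "sphere":
        return dx**2 + dy**2 + dz**2 <= r**2
    if spec.shape_kind == "ellipsoid":
        a, b, c = r, 0.8 * r, 0.6 * r
        return (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
    if spec.shape_kind == "bilobed":
        # two overlapping spheres -> single peanut-shaped component
        r1, r2, off = 0.72 * r, 0.6 * r, 0.5 * r
        lobe1 = (dx + off) ** 2 + dy**2 + dz**2 <= r1**2
        lobe2 = (dx - off) ** 2 + dy**2 + dz**2 <= r2**2
        return lobe1 | lobe2
    if spec.shape_kind == "torus":
        major, minor = 0.8 * r, 0.32 * r
        return (np.sqrt(dx**2 + dy**2) - major) ** 2 + dz**2 <= minor**2
    # two_blobs: disjoint spheres separated along x
    r1, r2, off = 0.6 * r, 0.48 * r, 0.72 * r
    blob1 = (dx + off) ** 2 + dy**2 + dz**2 <= r1**2
    blob2 = (dx - off) ** 2 + dy**2 + dz**2 <= r2**2
    return blob1 | blob2


def generate_phantom(spec: PhantomSpec) -> tuple[SUVVolume, BinaryMask]:
    """Generate a (volume, gold mask) pair from a :class:`PhantomSpec`.

    The intensity image is ``background + (tumor - background) * mask``
    convolved with an isotropic world-space Gaussian PSF (FWHM converted to
    per-axis voxel sigmas by the grid spacing), plus noise, clipped at 0.
    The same spec and seed always produce bit-identical output.
    """
    inside = _shape_mask(spec)
    if not inside.any():
        raise ValueError("tumor shape is empty on this grid")
    # shape must fit: the support may not touch the outer voxel layer
    edge = np.zeros(spec.grid.shape, dtype=bool)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    if (inside & edge).any():
        raise ValueError("tumor shape does not fit inside the grid")

    vals = np.where(inside, spec.tumor_uptake, spec.background_uptake).astype(np.float64)
    if spec.psf_fwhm_mm > 0:
        sigmas = [spec.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spec.grid.spacing]
        vals = ndimage.gaussian_filter(vals, sigmas, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            vals = vals + rng.normal(0.0, spec.noise_sigma, size=vals.shape)
        else:
            vals = rng.poisson(np.maximum(vals, 0.0) * spec.poisson_scale) / spec.poisson_scale
    vals = np.clip(vals, 0.0, None)
    return (
        SUVVolume(spec.grid, vals, units="SUV"),
        BinaryMask(spec.grid, inside.astype(np.uint8)),
    )


def roi_around(mask: BinaryMask, margin_voxels: int) -> BinaryMask:
    """Axis-aligned bounding box of ``mask`` dilated by ``margin_voxels``, clipped to the grid.

    Stands in for the rough user-drawn region of interest encircling the
    tumor that seeds the pre-segmentation.
    """
    if margin_voxels < 0:
        raise ValueError("margin must be >= 0")
    if mask.count() == 0:
        raise ValueError("cannot build an ROI around an empty mask")
    idx = np.argwhere(mask.values > 0)
    lo = np.maximum(idx.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + margin_voxels, np.array(mask.grid.shape) - 1)
    roi = np.zeros(mask.grid.shape, dtype=np.uint8)
    roi[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = 1
    return BinaryMask(mask.grid, roi)
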