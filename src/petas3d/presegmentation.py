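"""Pre-segmentation: from a rough user ROI to the ellipsoid level-set init.

The chain is: locate the maximum-uptake voxel inside the ROI, grow a
threshold-connected seed region around it (default 40%-of-max, the common
PET practice), fit an ellipsoid to the seed's second moments, and rasterize
it as a signed-distance field. The only hard requirement on the ellipsoid is
that it envelops part of the tumor including the maximum-intensity voxel;
the fit is grown uniformly until that holds.

Moments are computed in voxel units (index space), so the ellipsoid lives on
the same grid as the level-set field it initializes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from petas3d.active_surface import signed_distance
from petas3d.volume_io import BinaryMask, Grid3D, SUVVolume

__all__ = [
    "Ellipsoid",
    "find_max_voxel",
    "seed_region",
    "fit_ellipsoid",
    "ellipsoid_to_levelset",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid in voxel coordinates: center, semi-axes, principal-axis rotation."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    orientation: np.ndarray  # 3x3 rotation, columns = principal axes

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        R = np.asarray(self.orientation, dtype=np.float64)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("orientation must have determinant +1")
        object.__setattr__(self, "orientation", R)

    def contains(self, point: np.ndarray) -> bool:
        q = self.orientation.T @ (np.asarray(point, dtype=np.float64) - np.asarray(self.center))
        return bool(np.sum((q / np.asarray(self.semi_axes)) ** 2) <= 1.0)

    def quadric_values(self, grid: Grid3D) -> np.ndarray:
        """Normalized ellipsoid coordinate ||D^-1 R^T (x - c)|| per voxel (1 on the surface)."""
        ii, jj, kk = np.meshgrid(
            np.arange(grid.shape[0]),
            np.arange(grid.shape[1]),
            np.arange(grid.shape[2]),
            indexing="ij",
        )
        pts = np.stack([ii, jj, kk], axis=-1).astype(np.float64) - np.asarray(self.center)
        local = pts @ self.orientation  # (x - c) projected on principal axes
        return np.sqrt(np.sum((local / np.asarray(self.semi_axes)) ** 2, axis=-1))


def find_max_voxel(vol: SUVVolume, roi: BinaryMask) -> tuple[int, int, int]:
    """Index of the maximum-uptake voxel within the ROI; ties break to the lowest flat index."""
    if vol.grid != roi.grid:
        raise ValueError("volume and ROI must share a grid")
    if roi.count() == 0:
        raise ValueError("ROI is empty")
    masked = np.where(roi.bool, vol.values, -np.inf)
    flat = int(np.argmax(masked))  # first occurrence = lowest flat (C-order) index
    return tuple(int(c) for c in np.unravel_index(flat, vol.grid.shape))


def seed_region(vol: SUVVolume, roi: BinaryMask, frac: float = 0.4) -> BinaryMask:
    """26-connected component around the max voxel of {x in ROI : vol(x) >= frac * max}."""
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    peak = find_max_voxel(vol, roi)
    vmax = vol.values[peak]
    cand = roi.bool & (vol.values >= frac * vmax)
    labels, _ = ndimage.label(cand, structure=_CONN26)
    comp = labels == labels[peak]
    return BinaryMask(vol.grid, comp.astype(np.uint8))


def fit_ellipsoid(
    seed: BinaryMask,
    scale: float = 2.5,
    max_voxel: tuple[int, int, int] | None = None,
    min_semi_axis: float = 2.0,
) -> Ellipsoid:
    """Moment-based ellipsoid fit to a seed mask.

    Center = voxel centroid (intensity-free); axes = principal axes of the
    second-moment tensor; semi-axes = scale * sqrt(eigenvalues), floored at
    ``min_semi_axis`` voxels. With scale = sqrt(5) ~ 2.24 a solid ball maps
    back onto itself; the slightly larger default envelops the seed. Seeds
    of fewer than 4 voxels, or coplanar ones, fall back to a radius-3 sphere
    at the centroid. If ``max_voxel`` is given and falls outside, the
    semi-axes are grown uniformly until it is contained.
    """
    pts = np.argwhere(seed.values > 0).astype(np.float64)
    if len(pts) == 0:
        raise ValueError("cannot fit an ellipsoid to an empty seed")
    center = pts.mean(axis=0)
    fallback = False
    if len(pts) < 4:
        fallback = True
    else:
        cov = np.cov(pts.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] < 1e-9:  # coplanar / degenerate
            fallback = True
    if fallback:
        semi = np.array([3.0, 3.0, 3.0])
        R = np.eye(3)
    else:
        semi = np.maximum(scale * np.sqrt(evals), min_semi_axis)
        R = evecs
        if np.linalg.det(R) < 0:
            R = R.copy()
            R[:, 0] = -R[:, 0]
    ell = Ellipsoid(tuple(center), tuple(semi), R)
    if max_voxel is not None:
        p = np.asarray(max_voxel, dtype=np.float64)
        q = ell.orientation.T @ (p - center)
        rho = float(np.sqrt(np.sum((q / semi) ** 2)))
        if rho > 1.0:
            semi = semi * (rho * 1.05)  # grow uniformly until contained
            ell = Ellipsoid(tuple(center), tuple(semi), R)
    return ell


def ellipsoid_to_levelset(e: Ellipsoid, grid: Grid3D) -> np.ndarray:
    """Signed-distance level-set field of an ellipsoid (voxel units, negative inside)."""
    c = np.asarray(e.center)
    if np.any(c < 0) or np.any(c > np.asarray(grid.shape) - 1):
        raise ValueError("ellipsoid center must lie inside the grid")
    rho = e.quadric_values(grid)
    inside = rho <= 1.0
    if not inside.any():
        # ellipsoid smaller than a voxel: seed the nearest voxel to the center
        inside = np.zeros(grid.shape, dtype=bool)
        inside[tuple(np.clip(np.rint(c).astype(int), 0, np.asarray(grid.shape) - 1))] = True
    if inside.all():
        raise ValueError("ellipsoid covers the whole grid; cannot build a level set")
    return signed_distance(inside)
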