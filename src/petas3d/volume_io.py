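"""NIfTI volume I/O, SUV conversion, and the grid conventions shared by all modules.

Conventions
-----------
* Volumes are indexed ``values[i, j, k]`` (0-based, C order).
* The grid is regular and axis-aligned with anisotropic spacing in mm;
  the world coordinate of voxel ``(i, j, k)`` is ``(i*sx, j*sy, k*sz)``.
* Binary masks use ``{0, 1}`` with 1 = inside/foreground.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "Grid3D",
    "SUVVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "to_suv",
]


@dataclass(frozen=True)
class Grid3D:
    """Regular 3D voxel grid: shape ``(nx, ny, nz)``, spacing ``(sx, sy, sz)`` in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("Grid3D requires 3D shape and spacing")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(n < 1 for n in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers, broadcastable to shape."""
        x = np.arange(self.shape[0])[:, None, None] * self.spacing[0]
        y = np.arange(self.shape[1])[None, :, None] * self.spacing[1]
        z = np.arange(self.shape[2])[None, None, :] * self.spacing[2]
        return x, y, z


@dataclass
class SUVVolume:
    """3D scalar PET field on a :class:`Grid3D`.

    ``units`` flags whether values are dimensionless SUV or raw activity
    concentration (Bq/mL). SUV values must be finite and non-negative.
    """

    grid: Grid3D
    values: np.ndarray
    units: str = "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.units == "SUV" and np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")


@dataclass
class BinaryMask:
    """Binary {0,1} field on a :class:`Grid3D`; 1 = inside."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.shape != self.grid.shape:
            raise ValueError(f"mask shape {arr.shape} != grid shape {self.grid.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.values = arr.astype(np.uint8)

    @property
    def bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def count(self) -> int:
        return int(self.values.sum())


def _affine(grid: Grid3D) -> np.ndarray:
    return np.diag(list(grid.spacing) + [1.0])


def read_volume(path: str | os.PathLike) -> SUVVolume:
    """Read a 3D NIfTI-1 scalar image as an :class:`SUVVolume`.

    Spacing is taken from the file header (pixdim); values are cast to
    float64. Raises a descriptive error on missing files, non-3D images, or
    non-positive spacing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    grid = Grid3D(tuple(data.shape), tuple(float(z) for z in zooms))
    return SUVVolume(grid, data.astype(np.float64), units="SUV")


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI file as a binary mask (any nonzero voxel becomes 1)."""
    vol = read_volume(path)
    return BinaryMask(vol.grid, (vol.values != 0).astype(np.uint8))


def write_volume(vol: SUVVolume | BinaryMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI-1 with the grid spacing in the header.

    Masks are stored as 8-bit integers, volumes as float32. Non-finite
    values are rejected before anything touches the disk.
    """
    path = os.fspath(path)
    if isinstance(vol, BinaryMask):
        data = vol.values.astype(np.uint8)
    else:
        if not np.all(np.isfinite(vol.values)):
            raise ValueError("refusing to write non-finite volume values")
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.grid))
    img.header.set_zooms(vol.grid.spacing)
    try:
        nib.save(img, path)
    except OSError as exc:  # pragma: no cover - depends on fs state
        raise OSError(f"failed to write NIfTI file {path}: {exc}") from exc


def to_suv(activity: SUVVolume, injected_dose_bq: float, body_weight_g: float) -> SUVVolume:
    """Convert an activity-concentration image (Bq/mL) to body-weight SUV.

    SUV(x) = activity(x) * body_weight / injected_dose, assuming 1 g = 1 mL
    of tissue and a decay-corrected input. The result is dimensionless and
    shares the input grid.
    """
    if injected_dose_bq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_bq}")
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_g}")
    suv = activity.values * (body_weight_g / injected_dose_bq)
    return SUVVolume(activity.grid, suv, units="SUV")
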