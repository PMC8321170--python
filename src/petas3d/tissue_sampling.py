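"""Extraction of 3x3x3 voxel windows as 27-element training vectors.

Every interior voxel (window fully inside the grid) yields one sample. The
three-class tissue label depends only on how many of the window's 27 voxels
lie inside the gold-standard mask:

* 0 lesion voxels            -> ``background``
* 1..17 lesion voxels        -> ``border_line`` (window straddles the boundary)
* 18..27 lesion voxels       -> ``lesion``

Window flattening order is fixed and documented: the first grid axis (i)
varies fastest, then j, then k — element ``(di, dj, dk)`` of the window sits
at vector position ``di + 3*dj + 9*dk`` — so serialized models are portable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from petas3d.volume_io import BinaryMask, SUVVolume

__all__ = [
    "BACKGROUND",
    "BORDER_LINE",
    "LESION",
    "LABEL_NAMES",
    "BORDER_LINE_MAX_LESION_VOXELS",
    "TrainingSample",
    "SampleSet",
    "label_from_window",
    "extract_samples",
    "class_counts",
    "flatten_window",
]

BACKGROUND = 0
BORDER_LINE = 1
LESION = 2
LABEL_NAMES = {BACKGROUND: "background", BORDER_LINE: "border_line", LESION: "lesion"}

#: windows with 1..17 of their 27 voxels inside the gold standard are border-line
BORDER_LINE_MAX_LESION_VOXELS = 17


@dataclass(frozen=True)
class TrainingSample:
    vector: np.ndarray  # 27 intensities, i-fastest order
    label: int
    center: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.vector.shape != (27,):
            raise ValueError("sample vector must have exactly 27 elements")
        if self.label not in LABEL_NAMES:
            raise ValueError(f"unknown label {self.label}")


class SampleSet:
    """Array-backed sequence of :class:`TrainingSample`.

    Stores vectors ``(n, 27)``, integer labels ``(n,)`` and window centers
    ``(n, 3)`` contiguously; indexing materializes individual samples.
    """

    def __init__(self, vectors: np.ndarray, labels: np.ndarray, centers: np.ndarray):
        vectors = np.asarray(vectors, dtype=np.float64).reshape(-1, 27)
        labels = np.asarray(labels, dtype=np.int64).reshape(-1)
        centers = np.asarray(centers, dtype=np.int64).reshape(-1, 3)
        if not (len(vectors) == len(labels) == len(centers)):
            raise ValueError("vectors, labels and centers must have equal length")
        self.vectors = vectors
        self.labels = labels
        self.centers = centers

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> TrainingSample:
        return TrainingSample(self.vectors[i], int(self.labels[i]), tuple(self.centers[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def label_from_window(lesion_count: int) -> int:
    """Three-way tissue label from the number of gold-mask voxels in a window."""
    if not 0 <= lesion_count <= 27:
        raise ValueError(f"lesion count must be in 0..27, got {lesion_count}")
    if lesion_count == 0:
        return BACKGROUND
    if lesion_count <= BORDER_LINE_MAX_LESION_VOXELS:
        return BORDER_LINE
    return LESION


def flatten_window(window: np.ndarray) -> np.ndarray:
    """Flatten a 3x3x3 window with the i-fastest convention."""
    return np.asarray(window).flatten(order="F")


def _window_vectors(values: np.ndarray) -> np.ndarray:
    """All 3x3x3 windows of a 3D array as (n, 27) rows, i-fastest order."""
    w = sliding_window_view(values, (3, 3, 3))  # (nx-2, ny-2, nz-2, 3, 3, 3)
    w = w.reshape(-1, 3, 3, 3)
    # C-flatten of axes (dk, dj, di) makes di fastest == Fortran order on (di, dj, dk)
    return w.transpose(0, 3, 2, 1).reshape(-1, 27)


def extract_samples(vol: SUVVolume, gold: BinaryMask) -> SampleSet:
    """One labelled 27-vector per interior voxel of ``vol``.

    Windows that would leave the grid are skipped, so the sample count is
    exactly ``(nx-2)(ny-2)(nz-2)``. Labels come from the gold mask alone.
    """
    if vol.grid != gold.grid:
        raise ValueError("volume and gold mask must share a grid")
    nx, ny, nz = vol.grid.shape
    if min(nx, ny, nz) < 3:
        raise ValueError(f"grid must be >= 3 in every axis, got {vol.grid.shape}")

    vectors = _window_vectors(vol.values)
    counts = sliding_window_view(gold.values.astype(np.int64), (3, 3, 3)).sum(axis=(3, 4, 5))
    labels = np.where(
        counts.ravel() == 0,
        BACKGROUND,
        np.where(counts.ravel() <= BORDER_LINE_MAX_LESION_VOXELS, BORDER_LINE, LESION),
    )
    ci, cj, ck = np.meshgrid(
        np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1), indexing="ij"
    )
    centers = np.stack([ci.ravel(), cj.ravel(), ck.ravel()], axis=1)
    return SampleSet(vectors, labels, centers)


def class_counts(samples: SampleSet) -> tuple[int, int, int]:
    """Per-class sample totals as ``(n_lesion, n_border, n_background)``."""
    labels = samples.labels
    return (
        int(np.sum(labels == LESION)),
        int(np.sum(labels == BORDER_LINE)),
        int(np.sum(labels == BACKGROUND)),
    )
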