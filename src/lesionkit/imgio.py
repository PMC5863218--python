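"""NIfTI volume containers, I/O, and grid primitives.

Every map in the pipeline — lesion masks, tract-probability atlases,
disconnectome maps, correlation maps, entropy maps — lives on one shared
voxel grid (a symmetric template space such as MNI152). All downstream
operations are index-space operations: there is no resampling,
reorientation or registration anywhere in this package, so inputs must
already share a grid, and :func:`assert_same_grid` is the gatekeeper that
enforces it.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "MaskVolume",
    "TimeSeriesVolume",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "assert_same_grid",
    "binarize",
]

#: absolute tolerance on affine entries when comparing grids; absorbs
#: float32 header round-off without letting a 1 mm shift pass.
GRID_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not live on the same voxel grid."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class Volume:
    """A 3-D scalar field plus the affine mapping voxel indices to world mm.

    Attributes
    ----------
    data : ndarray, shape (X, Y, Z)
        Voxel values, stored in index order as read from disk.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-to-world transform.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got {self.data.ndim}-D")
        self.affine = _check_affine(self.affine)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per voxel along each axis (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class MaskVolume(Volume):
    """A Volume whose every voxel is exactly 0 or 1 (lesions, seeds, networks)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass
class TimeSeriesVolume:
    """A 4-D BOLD-like series: three spatial axes plus time."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"time-series data must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[3] < 2:
            raise ValueError("time axis must have length >= 2")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def spatial_grid(self) -> Volume:
        """A 3-D Volume carrying this series' grid (first frame)."""
        return Volume(self.data[..., 0], self.affine)


def read_volume(path: str | Path) -> Volume | TimeSeriesVolume:
    """Load a NIfTI-1 file as the typed container matching its dimensionality.

    3-D images become :class:`Volume`; 4-D images become
    :class:`TimeSeriesVolume` with the repetition time taken from the
    header's fourth zoom. Anything else is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = np.asarray(img.affine, dtype=float)
    if data.ndim == 3:
        return Volume(data, affine)
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return TimeSeriesVolume(data, affine, tr_seconds=tr)
    raise ValueError(f"unsupported dimensionality: {data.ndim}-D in {path}")


def write_volume(v: Volume | TimeSeriesVolume, path: str | Path) -> None:
    """Write a volume to NIfTI-1 (.nii or .nii.gz).

    Gzipped output is written with a zeroed gzip timestamp so that
    identical data always produce byte-identical files — a requirement
    for reproducible, seed-determined pipelines.
    """
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.data), v.affine)
    if isinstance(v, TimeSeriesVolume):
        zooms = list(img.header.get_zooms())
        zooms[3] = v.tr_seconds
        img.header.set_zooms(zooms)
    try:
        if path.name.endswith(".gz"):
            path.write_bytes(gzip.compress(img.to_bytes(), mtime=0))
        else:
            nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def assert_same_grid(a: Volume | TimeSeriesVolume, b: Volume | TimeSeriesVolume) -> None:
    """Raise :class:`GridMismatchError` unless a and b share shape and affine.

    Only the three spatial axes are compared; affines must agree within
    ``GRID_ATOL`` mm entrywise.
    """
    sa, sb = a.shape[:3], b.shape[:3]
    if sa != sb:
        raise GridMismatchError(f"shape mismatch: {sa} vs {sb}")
    if not np.allclose(a.affine, b.affine, rtol=0.0, atol=GRID_ATOL):
        raise GridMismatchError(
            f"affine mismatch beyond {GRID_ATOL}:\n{a.affine}\nvs\n{b.affine}"
        )


def binarize(v: Volume, threshold: float, strict: bool = True) -> MaskVolume:
    """Threshold a volume into a binary mask on the same grid.

    ``strict`` keeps voxels with value > threshold; otherwise >= threshold.
    """
    if strict:
        m = v.data > threshold
    else:
        m = v.data >= threshold
    return MaskVolume(m.astype(np.uint8), v.affine)
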