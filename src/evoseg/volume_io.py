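"""Density-map and label-volume I/O in MRC/CCP4 2014 format.

Two containers are shared by the whole package:

``DensityMap``
    a 3D scalar grid of electron density with voxel spacing, physical
    origin and an isosurface threshold that defines the molecular
    foreground.
``LabelMap``
    a 3D non-negative integer grid of the same shape; 0 is background,
    positive values identify segments.  It is the universal
    representation of both predicted segmentations and ground truth.

Grids are indexed ``(z, y, x)`` matching MRC section/row/column order.
Density maps are written as mode-2 (float32) volumes; label maps are
written as float32 volumes with integral values and validated for
integrality on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "DensityMap",
    "LabelMap",
    "read_density",
    "write_density",
    "read_labels",
    "write_labels",
    "foreground_mask",
    "canonicalize_labels",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable or inconsistent volume files."""


class EmptyMapError(ValueError):
    """Raised when the foreground of a map is empty."""


@dataclass(eq=False)
class DensityMap:
    """3D electron-density grid.

    Parameters
    ----------
    grid
        Densities, float32, indexed ``(z, y, x)``.
    voxel_size
        Voxel edge lengths in Angstrom, ordered ``(z, y, x)`` to match
        the grid axes.
    origin
        Physical coordinate (Angstrom, ``(z, y, x)``) of grid index
        ``(0, 0, 0)``.
    threshold
        Contour level above which a voxel belongs to the molecule.
        ``None`` means "not set"; :func:`foreground_mask` can estimate
        one with Otsu's method.
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("density grid must be 3D with each axis >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def with_threshold(self, threshold: float) -> "DensityMap":
        return replace(self, threshold=float(threshold))


@dataclass(eq=False)
class LabelMap:
    """3D integer segmentation grid; 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("labels must be integral")
        if labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 is background)")
        self.labels = labels.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        """Sorted positive labels present in the map."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def n_segments(self) -> int:
        return int(self.label_ids().size)


def _grid_to_ccp4(data_zyx: np.ndarray, voxel_size, origin) -> gemmi.Ccp4Map:
    vz, vy, vx = voxel_size
    nz, ny, nx = data_zyx.shape
    # gemmi's grid is indexed (x, y, z)
    grid = gemmi.FloatGrid(np.ascontiguousarray(data_zyx.T.astype(np.float32)))
    grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    oz, oy, ox = origin
    ccp4.set_header_float(50, float(ox))
    ccp4.set_header_float(51, float(oy))
    ccp4.set_header_float(52, float(oz))
    return ccp4


def _read_ccp4(path) -> tuple[np.ndarray, tuple, tuple]:
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise VolumeFormatError(f"cannot read MRC/CCP4 volume {path!r}: {exc}") from exc
    arr_xyz = np.array(ccp4.grid, copy=True)
    if arr_xyz.ndim != 3:
        raise VolumeFormatError(f"{path!r}: expected a 3D volume")
    sx, sy, sz = ccp4.grid.spacing
    origin = (
        float(ccp4.header_float(52)),
        float(ccp4.header_float(51)),
        float(ccp4.header_float(50)),
    )
    return arr_xyz.T, (float(sz), float(sy), float(sx)), origin


def read_density(path) -> DensityMap:
    """Read an MRC/CCP4 density volume.

    The contour threshold is not stored in the format and is left unset.
    """
    grid, voxel_size, origin = _read_ccp4(path)
    return DensityMap(grid=grid, voxel_size=voxel_size, origin=origin)


def write_density(dmap: DensityMap, path) -> None:
    """Write a density map as a mode-2 (float32) MRC volume."""
    _grid_to_ccp4(dmap.grid, dmap.voxel_size, dmap.origin).write_ccp4_map(str(path))


def write_labels(labels: LabelMap, path, voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    """Write a label volume as a float32 MRC with integral values."""
    data = labels.labels.astype(np.float32)
    _grid_to_ccp4(data, voxel_size, origin).write_ccp4_map(str(path))


def read_labels(path) -> LabelMap:
    """Read a label volume; values must be non-negative integers."""
    grid, _, _ = _read_ccp4(path)
    if not np.all(grid == np.round(grid)):
        raise VolumeFormatError(f"{path!r}: label volume has non-integral values")
    return LabelMap(labels=np.round(grid).astype(np.int32))


def foreground_mask(dmap: DensityMap, threshold: float | None = None) -> np.ndarray:
    """Boolean mask of voxels above the contour level.

    Uses, in order of preference: the explicit ``threshold`` argument,
    the map's own threshold, or an Otsu estimate over the nonzero
    densities.  Every segmentation operation in the package acts only on
    this mask.
    """
    if threshold is None:
        threshold = dmap.threshold
    if threshold is None:
        nonzero = dmap.grid[dmap.grid != 0]
        if nonzero.size == 0:
            raise EmptyMapError("all-zero map: cannot estimate a threshold")
        threshold = float(threshold_otsu(nonzero))
    return dmap.grid > threshold


def require_foreground(dmap: DensityMap, threshold: float | None = None) -> np.ndarray:
    """Like :func:`foreground_mask` but raises on an empty mask."""
    mask = foreground_mask(dmap, threshold)
    if not mask.any():
        raise EmptyMapError("empty foreground: no voxel above the contour level")
    return mask


def canonicalize_labels(labels: LabelMap) -> LabelMap:
    """Renumber positive labels to 1..K preserving the partition."""
    lab = labels.labels
    ids = np.unique(lab)
    pos = ids[ids > 0]
    lookup = np.zeros(int(ids.max()) + 1 if ids.size else 1, dtype=np.int32)
    lookup[pos] = np.arange(1, pos.size + 1, dtype=np.int32)
    return LabelMap(labels=lookup[lab])
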