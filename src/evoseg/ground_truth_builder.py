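"""Ground truth from atomic models, and the dataset inclusion filters.

When a density map has an associated atomic structure (PDB/mmCIF), the
chains of that structure define the subunits: every foreground voxel is
labeled after the chain whose nearest atom is closest to the voxel
centre in physical coordinates, and voxels farther than a cutoff
(default 5 Angstrom) from every atom stay background.  The resulting
LabelMap is interchangeable with a phantom's ground truth.

Dataset entries are screened with the inclusion criteria used to curate
training maps: at least 2 subunits, a reported resolution of 4.5-10
Angstrom, and a map/model volume ratio within [0.8, 1.2].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .metrics import volume_ratio_filter
from .volume_io import DensityMap, LabelMap, require_foreground

__all__ = [
    "DatasetEntry",
    "annotate_from_model",
    "model_volume",
    "apply_filters",
]

RESOLUTION_RANGE = (4.5, 10.0)
DEFAULT_CUTOFF = 5.0


@dataclass
class DatasetEntry:
    """One candidate map/model pair with its screening metadata."""

    map: DensityMap | None
    model_path: str = ""
    resolution: float = float("nan")
    n_subunits: int = 0
    map_volume: int = 0
    model_volume: int = 0
    accepted: bool = False
    rejection_reason: str = ""


def _chain_coords(structure_or_path) -> list[tuple[str, np.ndarray]]:
    """(chain name, atom coordinates) per chain of the first model."""
    if isinstance(structure_or_path, gemmi.Structure):
        structure = structure_or_path
    else:
        structure = gemmi.read_structure(str(structure_or_path))
    if len(structure) == 0:
        raise ValueError("atomic model contains no models")
    chains = []
    for chain in structure[0]:
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z]
                           for res in chain for a in res], dtype=np.float64)
        if coords.size:
            chains.append((chain.name, coords))
    if not chains:
        raise ValueError("atomic model contains no atoms")
    return chains


def _voxel_coords(dmap: DensityMap, mask: np.ndarray) -> np.ndarray:
    """Physical (x, y, z) coordinates of masked voxel centres."""
    zz, yy, xx = np.nonzero(mask)
    vz, vy, vx = dmap.voxel_size
    oz, oy, ox = dmap.origin
    return np.stack([ox + xx * vx, oy + yy * vy, oz + zz * vz], axis=1)


def annotate_from_model(dmap: DensityMap, structure_or_path,
                        cutoff: float = DEFAULT_CUTOFF) -> LabelMap:
    """Label each foreground voxel after its nearest chain.

    Chains are ordered by name; a voxel equidistant from two chains
    takes the lower chain index.  Voxels beyond ``cutoff`` Angstrom of
    every atom remain background.
    """
    mask = require_foreground(dmap)
    chains = sorted(_chain_coords(structure_or_path), key=lambda c: c[0])
    pts = _voxel_coords(dmap, mask)
    dists = np.stack([cKDTree(coords).query(pts)[0] for _, coords in chains])
    nearest = np.argmin(dists, axis=0)  # argmin ties -> first (lower) chain
    within = dists[nearest, np.arange(pts.shape[0])] <= cutoff
    labels = np.zeros(dmap.shape, dtype=np.int32)
    zz, yy, xx = np.nonzero(mask)
    labels[zz[within], yy[within], xx[within]] = nearest[within].astype(np.int32) + 1
    return LabelMap(labels=labels)


def model_volume(dmap: DensityMap, structure_or_path,
                 cutoff: float = DEFAULT_CUTOFF) -> int:
    """Voxel count of the structure-derived envelope (within cutoff of any atom)."""
    chains = _chain_coords(structure_or_path)
    coords = np.concatenate([c for _, c in chains])
    mask = np.ones(dmap.shape, dtype=bool)
    pts = _voxel_coords(dmap, mask)
    d, _ = cKDTree(coords).query(pts)
    return int(np.sum(d <= cutoff))


def apply_filters(entry: DatasetEntry) -> DatasetEntry:
    """Screen an entry against the dataset inclusion criteria.

    Pure predicate: returns an updated copy with ``accepted`` and, on
    rejection, a semicolon-joined ``rejection_reason``.
    """
    reasons = []
    if np.isnan(entry.resolution):
        raise ValueError("entry is missing a resolution")
    if entry.n_subunits < 2:
        reasons.append("fewer than 2 subunits")
    if not RESOLUTION_RANGE[0] <= entry.resolution <= RESOLUTION_RANGE[1]:
        reasons.append(f"resolution outside {RESOLUTION_RANGE[0]}-{RESOLUTION_RANGE[1]} A")
    if entry.map_volume > 0 and entry.model_volume > 0:
        if not volume_ratio_filter(entry.map_volume, entry.model_volume):
            reasons.append("map/model volume ratio outside [0.8, 1.2]")
    else:
        reasons.append("missing map or model volume")
    return replace(entry, accepted=not reasons, rejection_reason="; ".join(reasons))
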