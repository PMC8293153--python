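"""Synthetic multi-subunit density phantoms with exact ground truth.

A phantom emulates a macromolecular assembly at intermediate resolution:
each subunit is a union of overlapping isotropic Gaussian blobs, subunits
are placed adjacent to one another so they share fuzzy boundaries (the
failure mode that makes real maps hard to segment), the summed blob field
is blurred to a target resolution and corrupted with additive Gaussian
noise.  The per-voxel ground truth assigns every pre-noise foreground
voxel to the subunit whose blurred blob field dominates there, so the
truth is exact by construction and every downstream module is testable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume_io import DensityMap, LabelMap

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom", "generate_dataset"]


class PlacementError(RuntimeError):
    """Raised when subunit centers cannot be placed inside the grid."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic assembly.

    ``blobs_per_subunit`` and ``blob_radius`` are inclusive ranges
    sampled per subunit / per blob.  ``blob_radius`` is the Gaussian
    kernel's ~2-sigma extent in voxels.  ``noise_sd`` is the standard
    deviation of the additive noise relative to the peak of the clean
    blurred density; the noise is spatially correlated over
    ``noise_corr`` voxels (0 gives white noise), emulating the
    mid-frequency artefacts of experimental reconstructions that make
    watershed over-segment.  ``threshold_frac`` places the contour level
    as a fraction of the clean peak.
    """

    n_subunits: int = 3
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    blobs_per_subunit: tuple[int, int] = (3, 5)
    blob_radius: tuple[float, float] = (3.5, 5.5)
    resolution_sigma: float = 1.0
    noise_sd: float = 0.05
    noise_corr: float = 1.0
    threshold_frac: float = 0.3
    voxel_size: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid too small")
        if self.blob_radius[0] <= 0 or self.blobs_per_subunit[0] < 1:
            raise ValueError("blob ranges must be positive")


@dataclass
class PhantomPair:
    """A phantom map together with its exact ground truth."""

    map: DensityMap
    truth: LabelMap
    subunit_volumes: list[int] = field(default_factory=list)


def _place_centers(spec: PhantomSpec, radii: np.ndarray, rng: np.random.Generator,
                   max_tries: int = 200) -> np.ndarray:
    """Subunit centers: chained placement at distance ~ sum of radii."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    lo = radii.max() * 0.75
    centers = [shape / 2.0]
    for i in range(1, spec.n_subunits):
        placed = False
        for _ in range(max_tries):
            anchor_idx = int(rng.integers(0, len(centers)))
            anchor = centers[anchor_idx]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            # adjacent but not concentric: centers roughly touching
            dist = 1.05 * (radii[anchor_idx] + radii[i])
            cand = anchor + direction * dist
            if np.all(cand >= lo) and np.all(cand <= shape - lo):
                if all(np.linalg.norm(cand - c) >= 0.6 * (radii[i] + radii[j])
                       for j, c in enumerate(centers)):
                    centers.append(cand)
                    placed = True
                    break
        if not placed:
            raise PlacementError(
                f"could not place subunit {i + 1} in grid {spec.grid_shape}")
    return np.asarray(centers)


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None) -> PhantomPair:
    """Generate one phantom map plus ground-truth labels.

    Deterministic given ``spec.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    radii = rng.uniform(*spec.blob_radius, size=spec.n_subunits)
    centers = _place_centers(spec, radii, rng)

    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in spec.grid_shape),
                             indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1)

    fields = np.zeros((spec.n_subunits,) + tuple(spec.grid_shape), dtype=np.float64)
    for s in range(spec.n_subunits):
        n_blobs = int(rng.integers(spec.blobs_per_subunit[0],
                                   spec.blobs_per_subunit[1] + 1))
        blob_centers = [centers[s]]
        for _ in range(n_blobs - 1):
            base = blob_centers[int(rng.integers(0, len(blob_centers)))]
            offset = rng.normal(size=3)
            offset /= np.linalg.norm(offset)
            r = rng.uniform(*spec.blob_radius)
            blob_centers.append(base + offset * 1.6 * r)
        sd = radii[s] / 2.0
        for c in blob_centers:
            # varied amplitudes carve domain-scale saddles inside a subunit
            amp = rng.uniform(0.6, 1.0)
            d2 = np.sum((coords - c) ** 2, axis=-1)
            fields[s] += amp * np.exp(-d2 / (2.0 * sd * sd))

    # blur each subunit field separately (their sum is the blurred map) and
    # normalise to unit peak so subunits contribute comparable density
    for s in range(spec.n_subunits):
        if spec.resolution_sigma > 0:
            fields[s] = ndi.gaussian_filter(fields[s], spec.resolution_sigma)
        fields[s] /= fields[s].max()
    clean = fields.sum(axis=0)
    peak = 1.0  # single-subunit peak; overlaps may exceed it
    threshold = spec.threshold_frac * peak

    noise = rng.normal(0.0, 1.0, size=clean.shape)
    if spec.noise_corr > 0:
        noise = ndi.gaussian_filter(noise, spec.noise_corr)
    if spec.noise_sd > 0:
        noise *= spec.noise_sd * peak / noise.std()
    else:
        noise[:] = 0.0
    noisy = clean + noise

    fg = clean > threshold
    truth = np.zeros(spec.grid_shape, dtype=np.int32)
    # argmax breaks ties toward the lowest subunit index
    truth[fg] = np.argmax(fields[:, fg], axis=0).astype(np.int32) + 1

    vs = float(spec.voxel_size)
    dmap = DensityMap(grid=noisy.astype(np.float32), voxel_size=(vs, vs, vs),
                      threshold=threshold)
    volumes = [int(np.sum(truth == s + 1)) for s in range(spec.n_subunits)]
    return PhantomPair(map=dmap, truth=LabelMap(labels=truth), subunit_volumes=volumes)


def default_spec_sampler(rng: np.random.Generator) -> PhantomSpec:
    """Sample assembly parameters: 2-4 subunits on a 32^3 grid."""
    return PhantomSpec(
        n_subunits=int(rng.integers(2, 5)),
        grid_shape=(32, 32, 32),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(n_maps: int, spec_sampler=None, seed: int | None = None) -> list[PhantomPair]:
    """Generate ``n_maps`` independent phantoms, reproducible from ``seed``."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    if spec_sampler is None:
        spec_sampler = default_spec_sampler
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_maps):
        spec = spec_sampler(rng)
        for attempt in range(10):
            try:
                pairs.append(generate_phantom(spec))
                break
            except PlacementError:
                spec = spec_sampler(rng)
        else:
            raise PlacementError("repeated placement failures while sampling dataset")
    return pairs
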