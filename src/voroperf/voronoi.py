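"""Poisson-disk seeding and voxel Voronoi parcellation of lung masks.

Each lung is discretized independently: seed points are drawn inside the lung
with Bridson's Poisson-disk algorithm (minimum pairwise spacing ``r``, in
isotropic-voxel units), and every lung voxel is then labelled with its nearest
seed by Euclidean distance, producing spatially contiguous subvolumes whose
characteristic size is controlled by ``r``.  As ``r`` approaches 1 the
subvolumes approach single voxels; once ``r`` exceeds the lung diameter each
lung collapses to a single subvolume.

Seeding is stochastic, so partitions are generated over several independent
realizations (default 5) and downstream scores are averaged across them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DegenerateCaseError, LungMask

DEFAULT_K_ATTEMPTS = 30  # Bridson's canonical rejection budget per active point
DEFAULT_N_REALIZATIONS = 5


@dataclass
class SeedSet:
    """Poisson-disk seed points for one lung, in continuous voxel coordinates."""

    points: np.ndarray  # (n, 3) float
    radius_r: float
    rng_seed: int
    lung_label: int

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("SeedSet needs at least one 3D point")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class Partition:
    """Per-voxel subvolume labelling of one lung (0 outside, 1..K inside)."""

    subvolume_labels: np.ndarray
    subvolume_sizes: np.ndarray  # voxel count per subvolume id (1-based ids)
    radius_r: float
    realization_index: int = 0

    @property
    def n_subvolumes(self) -> int:
        return int(self.subvolume_sizes.size)


def sample_seeds_bridson(
    mask: LungMask,
    lung_label: int,
    radius_r: float,
    rng_seed: int,
    k_attempts: int = DEFAULT_K_ATTEMPTS,
) -> SeedSet:
    """Draw a maximal-effort Poisson-disk sample restricted to one lung.

    The first point is a uniformly drawn lung voxel centre.  New candidates are
    drawn around active points in the spherical annulus ``[r, 2r)`` (uniform
    direction, radius ~ U[r, 2r)), ``k_attempts`` per activation; a candidate
    is accepted iff its containing voxel carries the lung label and it lies at
    distance >= r from every accepted point.  Deterministic given ``rng_seed``.
    """
    if radius_r < 1:
        raise ValueError(f"radius_r must be >= 1 voxel, got {radius_r}")
    lung_idx = np.argwhere(mask.labels == lung_label)
    if lung_idx.size == 0:
        raise DegenerateCaseError(f"lung label {lung_label} is empty")
    rng = np.random.default_rng(rng_seed)
    shape = np.asarray(mask.shape)

    # Background grid for O(1) neighbour lookup: cell edge r/sqrt(3) holds at
    # most one accepted point, so conflicts live within +/-2 cells.
    cell = radius_r / np.sqrt(3.0)
    gdims = np.maximum(1, np.ceil(shape / cell).astype(int))
    grid = -np.ones(gdims, dtype=np.int64)
    r2 = radius_r * radius_r

    def cell_of(p: np.ndarray) -> tuple[int, int, int]:
        c = np.minimum((p / cell).astype(int), gdims - 1)
        return int(c[0]), int(c[1]), int(c[2])

    def in_lung(p: np.ndarray) -> bool:
        vox = np.rint(p).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            return False
        return mask.labels[vox[0], vox[1], vox[2]] == lung_label

    def conflicts(p: np.ndarray, points: list[np.ndarray]) -> bool:
        ci, cj, ck = cell_of(p)
        for di in range(max(ci - 2, 0), min(ci + 3, gdims[0])):
            for dj in range(max(cj - 2, 0), min(cj + 3, gdims[1])):
                for dk in range(max(ck - 2, 0), min(ck + 3, gdims[2])):
                    q = grid[di, dj, dk]
                    if q >= 0:
                        d = p - points[q]
                        if d @ d < r2:
                            return True
        return False

    first = lung_idx[rng.integers(lung_idx.shape[0])].astype(np.float64)
    points: list[np.ndarray] = [first]
    grid[cell_of(first)] = 0
    active = [0]

    while active:
        a_pos = rng.integers(len(active))
        p0 = points[active[a_pos]]
        accepted = False
        for _ in range(k_attempts):
            direction = rng.standard_normal(3)
            norm = np.linalg.norm(direction)
            if norm == 0.0:
                continue
            radius = rng.uniform(radius_r, 2.0 * radius_r)
            cand = p0 + direction * (radius / norm)
            if not in_lung(cand):
                continue
            if conflicts(cand, points):
                continue
            points.append(cand)
            grid[cell_of(cand)] = len(points) - 1
            active.append(len(points) - 1)
            accepted = True
            break
        if not accepted:
            active.pop(a_pos)

    return SeedSet(np.array(points), radius_r, rng_seed, lung_label)


def assign_voronoi(
    mask: LungMask,
    lung_label: int,
    seeds: SeedSet,
    realization_index: int = 0,
    chunk: int = 16384,
) -> Partition:
    """Label every lung voxel with its nearest seed (1-based, seed order).

    Distances are Euclidean in voxel units; exact ties go to the lowest seed
    index (``argmin`` takes the first minimum).
    """
    lung_idx = np.argwhere(mask.labels == lung_label)
    if lung_idx.size == 0:
        raise DegenerateCaseError(f"lung label {lung_label} is empty")
    pts = seeds.points
    labels = np.zeros(mask.shape, dtype=np.int32)
    nearest = np.empty(lung_idx.shape[0], dtype=np.int64)
    coords = lung_idx.astype(np.float64)
    for start in range(0, coords.shape[0], chunk):
        block = coords[start : start + chunk]
        d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        nearest[start : start + block.shape[0]] = np.argmin(d2, axis=1)
    labels[lung_idx[:, 0], lung_idx[:, 1], lung_idx[:, 2]] = nearest + 1
    sizes = np.bincount(nearest, minlength=len(seeds)).astype(np.int64)
    return Partition(labels, sizes, seeds.radius_r, realization_index)


def partition_lung(
    mask: LungMask,
    lung_label: int,
    radius_r: float,
    rng_seed: int,
    realization_index: int = 0,
    k_attempts: int = DEFAULT_K_ATTEMPTS,
) -> Partition:
    seeds = sample_seeds_bridson(mask, lung_label, radius_r, rng_seed, k_attempts)
    return assign_voronoi(mask, lung_label, seeds, realization_index)


def partition_realizations(
    mask: LungMask,
    radius_r: float,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    base_seed: int = 0,
    k_attempts: int = DEFAULT_K_ATTEMPTS,
) -> list[tuple[Partition, Partition]]:
    """Independent (left, right) partition pairs; realization k uses
    ``rng_seed = base_seed + k`` for both lungs (the domains differ, so the
    partitions are independent in geometry).  An empty lung yields ``None`` in
    its slot, so single-lung masks remain usable for partition statistics."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    present = [lab for lab in (1, 2) if mask.lung_voxel_count(lab) > 0]
    if not present:
        raise DegenerateCaseError("mask has no lung voxels")
    out = []
    for k in range(n_realizations):
        pair = tuple(
            partition_lung(mask, lab, radius_r, base_seed + k, k, k_attempts)
            if lab in present
            else None
            for lab in (1, 2)
        )
        out.append(pair)
    return out


def mean_subvolume_count(
    mask: LungMask,
    radius_r: float,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    base_seed: int = 0,
) -> float:
    """Mean over realizations of the total (left + right) subvolume count."""
    counts = []
    for left, right in partition_realizations(mask, radius_r, n_realizations, base_seed):
        counts.append(sum(p.n_subvolumes for p in (left, right) if p is not None))
    return float(np.mean(counts))


__all__ = [
    "SeedSet",
    "Partition",
    "sample_seeds_bridson",
    "assign_voronoi",
    "partition_lung",
    "partition_realizations",
    "mean_subvolume_count",
]
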