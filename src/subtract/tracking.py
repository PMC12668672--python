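"""Probabilistic streamline tractography through a multi-fibre orientation field.

The propagation model follows standard probabilistic-tracking practice for
crossing-fibre fields: each voxel carries up to three fibre populations
(axial mean orientation, volume fraction, angular dispersion). At each step
the tracker discards populations below a volume-fraction threshold (default
1%), picks the surviving population best aligned with the previous direction,
draws a dispersed sample around its mean, and advances by one step (default
0.5 mm). A streamline terminates when it leaves the field, finds no fibre,
bends more than the curvature threshold (default 80 deg) in one step, enters
a stop or exclusion mask, or exhausts the step budget (default 2000 per
half-streamline). Tracking from a seed runs two half-streamlines in opposite
initial signs which are concatenated.

A streamline is *valid* for a protocol iff it visits every target mask
(unordered conjunction) and never enters an exclusion mask; entering a stop
mask truncates propagation but the truncated path still counts if targets
were already visited. Per-tract path distributions count, per voxel, the
number of distinct valid streamlines entering it, normalised by the total
number of valid streamlines so values are visitation probabilities in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .volumes import BinaryMask, ScalarVolume, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "FibreField",
    "TrackingParams",
    "Streamline",
    "PathDistribution",
    "NO_FIBRE",
    "sample_direction",
    "propagate",
    "track_protocol",
    "normalise",
    "run_symmetric",
]

MAX_POPULATIONS = 3

#: sentinel returned by sample_direction when no population survives
NO_FIBRE = None


@dataclass
class FibreField:
    """Up to three fibre populations per voxel.

    orientations : (nx, ny, nz, 3, 3) unit vectors (axial: v and -v equivalent)
    fractions    : (nx, ny, nz, 3) volume fractions in [0, 1]; 0 = absent
    dispersions  : (nx, ny, nz, 3) angular dispersion SD in degrees
    """

    grid: VoxelGrid
    orientations: np.ndarray
    fractions: np.ndarray
    dispersions: np.ndarray

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid.shape
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        if self.orientations.shape != (nx, ny, nz, MAX_POPULATIONS, 3):
            raise ValueError("orientations must have shape grid + (3, 3)")
        if self.fractions.shape != (nx, ny, nz, MAX_POPULATIONS):
            raise ValueError("fractions must have shape grid + (3,)")
        if self.dispersions.shape != (nx, ny, nz, MAX_POPULATIONS):
            raise ValueError("dispersions must have shape grid + (3,)")
        present = self.fractions > 0
        norms = np.linalg.norm(self.orientations[present], axis=-1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("present fibre orientations must be unit-norm")

    @classmethod
    def empty(cls, grid: VoxelGrid) -> "FibreField":
        nx, ny, nz = grid.shape
        return cls(
            grid=grid,
            orientations=np.zeros((nx, ny, nz, MAX_POPULATIONS, 3)),
            fractions=np.zeros((nx, ny, nz, MAX_POPULATIONS)),
            dispersions=np.zeros((nx, ny, nz, MAX_POPULATIONS)),
        )

    def population_count(self) -> np.ndarray:
        return (self.fractions > 0).sum(axis=-1)


@dataclass
class TrackingParams:
    """Tracking parameters; defaults are the human-scale settings
    (0.5 mm steps; 0.2 mm is the macaque-scale choice)."""

    step_size: float = 0.5
    curvature_threshold: float = 80.0
    max_steps: int = 2000
    volume_fraction_threshold: float = 0.01
    streamlines_per_seed_voxel: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0 < self.curvature_threshold <= 180:
            raise ValueError("curvature_threshold must be in (0, 180]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not 0 <= self.volume_fraction_threshold < 1:
            raise ValueError("volume_fraction_threshold must be in [0, 1)")

    @property
    def cos_curvature(self) -> float:
        return math.cos(math.radians(self.curvature_threshold))


@dataclass
class Streamline:
    """Ordered world points of one trajectory plus per-half termination reasons.

    ``reasons`` holds (backward-half, forward-half) reasons, each one of
    left-field / no-fibre / curvature / max-steps / stop-mask / exclusion.
    """

    points: np.ndarray
    reasons: tuple[str, str]

    @property
    def termination_reason(self) -> str:
        return self.reasons[1]

    @property
    def excluded(self) -> bool:
        return "exclusion" in self.reasons


@dataclass
class PathDistribution:
    """Per-voxel visitation map for one tract."""

    grid: VoxelGrid
    values: np.ndarray
    n_valid: int
    normalised: bool = False
    n_total: int = 0
    reason_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must equal grid shape")
        if np.any(self.values < 0):
            raise ValueError("visitation values must be non-negative")
        if self.normalised and self.values.size and self.values.max() > 1 + 1e-9:
            raise ValueError("normalised values must be <= 1")

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# direction sampling


def _dispersed(mean: np.ndarray, dispersion_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``mean`` by an angle ~ N(0, dispersion) about a random
    perpendicular axis (simple wrapped-normal axial dispersion stand-in)."""
    if dispersion_deg <= 0:
        return mean
    angle = rng.normal(0.0, math.radians(dispersion_deg))
    # random unit vector perpendicular to mean
    v = rng.normal(size=3)
    v -= mean * (v @ mean)
    nv = math.sqrt(v @ v)
    if nv < 1e-12:
        return mean
    v /= nv
    return mean * math.cos(angle) + v * math.sin(angle)


def sample_direction(
    field: FibreField,
    voxel: tuple[int, int, int],
    prev_dir: Optional[np.ndarray],
    params: TrackingParams,
    rng: np.random.Generator,
) -> Optional[np.ndarray]:
    """Draw a propagation direction at ``voxel``, or NO_FIBRE.

    Populations below the volume-fraction threshold are ignored. With a
    previous direction, the surviving population with maximal ``|dot|``
    alignment is followed; without one, a population is chosen at random
    with probability proportional to its volume fraction. The returned
    sample is sign-disambiguated so ``dot(result, prev_dir) >= 0``.
    """
    i, j, k = voxel
    fr = field.fractions[i, j, k]
    alive = np.nonzero(fr >= params.volume_fraction_threshold)[0]
    alive = alive[fr[alive] > 0]
    if alive.size == 0:
        return NO_FIBRE
    means = field.orientations[i, j, k]
    if prev_dir is None:
        w = fr[alive]
        idx = alive[rng.choice(alive.size, p=w / w.sum())] if alive.size > 1 else alive[0]
    else:
        dots = np.abs(means[alive] @ prev_dir)
        idx = alive[int(np.argmax(dots))]
    mean = means[idx]
    if prev_dir is not None and mean @ prev_dir < 0:
        mean = -mean
    d = _dispersed(mean, field.dispersions[i, j, k, idx], rng)
    if prev_dir is not None and d @ prev_dir < 0:
        d = -d
    n = math.sqrt(d @ d)
    return d / n


# ---------------------------------------------------------------------------
# propagation


def _half_streamline(
    field: FibreField,
    start: np.ndarray,
    d0: np.ndarray,
    params: TrackingParams,
    stop: Optional[np.ndarray],
    exclusion: Optional[np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], str]:
    """Propagate one half-streamline from ``start`` along initial ``d0``."""
    shape = field.grid.shape
    inv = field.grid._inverse
    pts: list[np.ndarray] = []
    pos = start
    d = d0
    reason = "max-steps"
    for _ in range(params.max_steps):
        pos = pos + params.step_size * d
        v = pos @ inv[:3, :3].T + inv[:3, 3]
        i, j, k = int(round(v[0])), int(round(v[1])), int(round(v[2]))
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            reason = "left-field"
            break
        pts.append(pos)
        if exclusion is not None and exclusion[i, j, k]:
            reason = "exclusion"
            break
        if stop is not None and stop[i, j, k]:
            reason = "stop-mask"
            break
        nd = sample_direction(field, (i, j, k), d, params, rng)
        if nd is NO_FIBRE:
            reason = "no-fibre"
            break
        if nd @ d < params.cos_curvature:
            reason = "curvature"  # step rejected: angle exceeds threshold
            break
        d = nd
    return pts, reason


def propagate(
    field: FibreField,
    seed_point: np.ndarray,
    params: TrackingParams,
    stop: Optional[BinaryMask] = None,
    exclusion: Optional[BinaryMask] = None,
    rng: Optional[np.random.Generator] = None,
) -> Streamline:
    """Track both half-streamlines from a world-space seed point."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    seed_point = np.asarray(seed_point, dtype=float)
    ijk = field.grid.world_to_index(seed_point)
    if not field.grid.inside(ijk):
        raise ValueError("seed point outside grid")
    stop_m = stop.membership if stop is not None else None
    excl_m = exclusion.membership if exclusion is not None else None
    d0 = sample_direction(field, tuple(ijk), None, params, rng)
    if d0 is NO_FIBRE:
        return Streamline(points=seed_point[None, :], reasons=("no-fibre", "no-fibre"))
    back, r_back = _half_streamline(field, seed_point, -d0, params, stop_m, excl_m, rng)
    fwd, r_fwd = _half_streamline(field, seed_point, d0, params, stop_m, excl_m, rng)
    points = np.array(back[::-1] + [seed_point] + fwd)
    return Streamline(points=points, reasons=(r_back, r_fwd))


# ---------------------------------------------------------------------------
# protocol-constrained tracking


def _visited_flat(grid: VoxelGrid, points: np.ndarray) -> np.ndarray:
    """Flat indices of in-grid voxels visited by a polyline's vertices."""
    v = grid.world_to_index(points)
    ok = (v >= 0).all(axis=1) & (v < np.asarray(grid.shape)).all(axis=1)
    v = v[ok]
    if v.size == 0:
        return np.empty(0, dtype=np.intp)
    flat = np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), grid.shape)
    return np.unique(flat)


def track_protocol(field: FibreField, protocol, params: TrackingParams) -> PathDistribution:
    """Launch ``streamlines_per_seed_voxel`` jittered streamlines per seed
    voxel and accumulate the distinct-streamline visitation map of the
    valid ones (unnormalised counts; see :func:`normalise`).
    """
    grid = field.grid
    if protocol.seed.grid != grid:
        raise ValueError("protocol masks and field are on different grids")
    seeds = protocol.seed.indices()
    if seeds.shape[0] == 0:
        raise ValueError("empty seed mask")

    target_flats = [
        np.flatnonzero(t.membership.ravel()) for t in protocol.targets
    ]
    excl = None
    if protocol.exclusions:
        m = np.zeros(grid.shape, dtype=bool)
        for e in protocol.exclusions:
            m |= e.membership
        excl = BinaryMask(grid, m)
    stop = protocol.stop

    counts = np.zeros(grid.shape, dtype=np.int64).ravel()
    n_valid = 0
    n_total = 0
    reason_counts: dict[str, int] = {}
    stream_idx = 0
    for s in seeds:
        for _ in range(params.streamlines_per_seed_voxel):
            rng = np.random.default_rng([params.rng_seed, stream_idx])
            stream_idx += 1
            n_total += 1
            jitter = rng.uniform(-0.5, 0.5, size=3)
            seed_world = grid.voxel_to_world(s + jitter)
            sl = propagate(field, seed_world, params, stop=stop, exclusion=excl, rng=rng)
            for r in sl.reasons:
                reason_counts[r] = reason_counts.get(r, 0) + 1
            if sl.excluded:
                continue
            visited = _visited_flat(grid, sl.points)
            if all(np.intersect1d(visited, tf, assume_unique=True).size > 0 for tf in target_flats):
                counts[visited] += 1
                n_valid += 1
    return PathDistribution(
        grid=grid,
        values=counts.reshape(grid.shape).astype(float),
        n_valid=n_valid,
        normalised=False,
        n_total=n_total,
        reason_counts=reason_counts,
    )


def normalise(pd: PathDistribution) -> PathDistribution:
    """Divide visitation counts by the number of valid streamlines."""
    if pd.normalised:
        raise ValueError("path distribution already normalised")
    if pd.n_valid == 0:
        logger.warning("normalise: zero valid streamlines; returning all-zero map")
        values = np.zeros(pd.grid.shape)
    else:
        values = pd.values / pd.n_valid
    return PathDistribution(
        grid=pd.grid,
        values=values,
        n_valid=pd.n_valid,
        normalised=True,
        n_total=pd.n_total,
        reason_counts=dict(pd.reason_counts),
    )


def run_symmetric(field: FibreField, protocol, params: TrackingParams) -> PathDistribution:
    """Seed<->final-target flipped tracking, averaging the two normalised runs
    (the anterior-commissure style protocol)."""
    if not protocol.symmetric:
        raise ValueError("protocol symmetric flag not set")
    if not protocol.targets:
        raise ValueError("symmetric run requires at least one target")
    fwd = normalise(track_protocol(field, protocol, params))
    rev_params = TrackingParams(
        step_size=params.step_size,
        curvature_threshold=params.curvature_threshold,
        max_steps=params.max_steps,
        volume_fraction_threshold=params.volume_fraction_threshold,
        streamlines_per_seed_voxel=params.streamlines_per_seed_voxel,
        rng_seed=params.rng_seed + 1,
    )
    rev = normalise(track_protocol(field, protocol.flipped(), rev_params))
    return PathDistribution(
        grid=field.grid,
        values=0.5 * (fwd.values + rev.values),
        n_valid=fwd.n_valid + rev.n_valid,
        normalised=True,
        n_total=fwd.n_total + rev.n_total,
        reason_counts={
            r: fwd.reason_counts.get(r, 0) + rev.reason_counts.get(r, 0)
            for r in set(fwd.reason_counts) | set(rev.reason_counts)
        },
    )


def path_density_volume(pd: PathDistribution) -> ScalarVolume:
    return ScalarVolume(pd.grid, pd.values.copy())
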