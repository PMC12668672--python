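"""Anterograde-tracer termination-probability maps.

Termination coordinates, each labelled with the injection ROI of its case
(frontal / parietal / temporal / sensorimotor cortex, ...), are binned to the
voxels of a target-structure mask (e.g. the putamen) and converted to one
probability map per injection ROI: in-mask counts divided by the label's
total in-mask terminations. Maps can be smoothed with a separable cubic
B-spline kernel (mask-restricted and renormalised, so per-label mass stays
exactly 1), and a dominant-label volume renders which injection ROI wins at
each voxel — the topography comparison against tractography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryMask, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "TerminationTable",
    "TerminationMap",
    "termination_probability",
    "smooth_map",
    "dominant_label",
]


@dataclass
class TerminationTable:
    """Records of (world coordinate, injection-ROI label, case id)."""

    records: pd.DataFrame  # columns: x, y, z, label, case
    label_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"x", "y", "z", "label"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"termination table missing columns {sorted(missing)}")
        if "case" not in self.records.columns:
            self.records = self.records.assign(case="")
        coords = self.records[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("termination coordinates must be finite")
        if not self.label_set:
            self.label_set = sorted(self.records["label"].unique())
        unknown = set(self.records["label"]) - set(self.label_set)
        if unknown:
            raise ValueError(f"labels outside the declared label set: {sorted(unknown)}")

    @classmethod
    def from_csv(cls, path, label_set: list[str] | None = None) -> "TerminationTable":
        return cls(records=pd.read_csv(path), label_set=label_set or [])


@dataclass
class TerminationMap:
    """Per-injection-ROI probability volumes over a target mask."""

    grid: VoxelGrid
    mask: BinaryMask
    maps: dict[str, np.ndarray]
    smoothed: bool = False
    dropped: dict[str, int] = field(default_factory=dict)

    def mass(self, label: str) -> float:
        return float(self.maps[label][self.mask.membership].sum())


def termination_probability(table: TerminationTable, target_mask: BinaryMask) -> TerminationMap:
    """Bin terminations to target-mask voxels; per label, divide counts by the
    label's total in-mask terminations. Out-of-mask terminations are dropped
    and counted in the ``dropped`` report."""
    if target_mask.is_empty:
        raise ValueError("empty target mask")
    grid = target_mask.grid
    maps: dict[str, np.ndarray] = {}
    dropped: dict[str, int] = {}
    for label in table.label_set:
        sub = table.records[table.records["label"] == label]
        counts = np.zeros(grid.shape)
        n_out = 0
        for xyz in sub[["x", "y", "z"]].to_numpy(dtype=float):
            ijk = grid.world_to_index(xyz)
            if grid.inside(ijk) and target_mask.membership[tuple(ijk)]:
                counts[tuple(ijk)] += 1
            else:
                n_out += 1
        total = counts.sum()
        if total == 0:
            logger.warning("label %r has zero in-mask terminations; all-zero map", label)
            maps[label] = counts
        else:
            maps[label] = counts / total
        dropped[label] = n_out
    return TerminationMap(grid=grid, mask=target_mask, maps=maps, smoothed=False, dropped=dropped)


def _bspline_kernel(scale_voxels: float) -> np.ndarray:
    """Cubic B-spline kernel sampled at integer voxel offsets, sum-normalised.

    The cubic B-spline B3 has support [-2, 2] in units of the scale; a scale
    small enough that no neighbour falls inside the support degenerates to
    the identity kernel.
    """
    if scale_voxels <= 0:
        raise ValueError("smoothing scale must be positive")
    radius = int(np.ceil(2.0 * scale_voxels - 1e-9))
    if radius < 1:
        return np.array([1.0])
    t = np.arange(-radius, radius + 1) / scale_voxels
    a = np.abs(t)
    k = np.where(
        a < 1.0,
        2.0 / 3.0 - a**2 + a**3 / 2.0,
        np.where(a < 2.0, (2.0 - a) ** 3 / 6.0, 0.0),
    )
    return k / k.sum()


def smooth_map(tmap: TerminationMap, smoothing_scale_mm: float) -> TerminationMap:
    """Separable cubic B-spline smoothing, mask-restricted and renormalised
    so each label's in-mask mass is exactly 1 again."""
    if tmap.smoothed:
        raise ValueError("map is already smoothed")
    if smoothing_scale_mm <= 0:
        raise ValueError("smoothing scale must be positive")
    voxel = tmap.grid.voxel_size
    out: dict[str, np.ndarray] = {}
    inside = tmap.mask.membership
    for label, vol in tmap.maps.items():
        sm = vol
        for axis in range(3):
            kernel = _bspline_kernel(smoothing_scale_mm / voxel[axis])
            sm = ndimage.convolve1d(sm, kernel, axis=axis, mode="constant", cval=0.0)
        sm = np.where(inside, sm, 0.0)
        total = sm.sum()
        out[label] = sm / total if total > 0 else sm
    return TerminationMap(
        grid=tmap.grid,
        mask=tmap.mask,
        maps=out,
        smoothed=True,
        dropped=dict(tmap.dropped),
    )


def dominant_label(tmap: TerminationMap, label_order: list[str] | None = None) -> np.ndarray:
    """Per-voxel argmax label index inside the mask (ties -> first label in
    the declared order); -1 outside the mask. Returns an int volume whose
    values index ``label_order``."""
    labels = label_order or list(tmap.maps)
    if not labels:
        raise ValueError("empty map set")
    stack = np.stack([tmap.maps[lab] for lab in labels], axis=0)
    winner = np.argmax(stack, axis=0)  # argmax returns the first maximum
    out = np.where(tmap.mask.membership, winner, -1)
    return out.astype(int)
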