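"""Voxel-grid data model and NIfTI I/O.

All spatial objects in the package live on a :class:`VoxelGrid`: a 3D array of
voxels with an affine mapping 0-based voxel indices to world coordinates in
millimetres. The convention throughout is voxel-centre: the world position of
voxel ``(i, j, k)`` is ``affine @ (i, j, k, 1)``, and a world point belongs to
the voxel whose centre is nearest (round-to-nearest index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "downsample",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D voxel array: shape plus index->world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    _inverse: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {shape}")
        object.__setattr__(self, "shape", shape)
        affine = np.eye(4) if self.affine is None else np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        try:
            inverse = np.linalg.inv(affine)
        except np.linalg.LinAlgError as exc:
            raise ValueError("affine is not invertible") from exc
        if np.any(self.voxel_size_from(affine) <= 0):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "_inverse", inverse)

    @staticmethod
    def voxel_size_from(affine: np.ndarray) -> np.ndarray:
        return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return self.voxel_size_from(self.affine)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 1.0) -> "VoxelGrid":
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(shape=shape, affine=aff)

    # -- index/world conversions (voxel-centre convention) -----------------

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates of world point(s)."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self._inverse[:3, :3].T + self._inverse[:3, 3]

    def world_to_index(self, xyz) -> np.ndarray:
        """Nearest voxel index of world point(s); may fall outside the grid."""
        return np.rint(self.world_to_voxel(xyz)).astype(np.intp)

    def inside(self, ijk) -> bool | np.ndarray:
        ijk = np.asarray(ijk)
        ok = (ijk >= 0) & (ijk < np.asarray(self.shape))
        return ok.all(axis=-1)

    def __eq__(self, other) -> bool:  # value semantics for grid matching
        return (
            isinstance(other, VoxelGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes()))


@dataclass
class ScalarVolume:
    """A real value per voxel on a grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class BinaryMask:
    """Boolean membership per voxel; an all-False mask is a valid empty mask."""

    grid: VoxelGrid
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.membership.shape} != grid shape {self.grid.shape}"
            )

    @property
    def is_empty(self) -> bool:
        return not self.membership.any()

    def count(self) -> int:
        return int(self.membership.sum())

    def indices(self) -> np.ndarray:
        """N x 3 array of member voxel indices."""
        return np.argwhere(self.membership)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> ScalarVolume:
    """Read a 3D NIfTI volume, promoting stored values to float."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has shape {data.shape}")
    grid = VoxelGrid(shape=data.shape, affine=np.asarray(img.affine))
    return ScalarVolume(grid=grid, values=data.astype(float))


def write_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(grid=vol.grid, membership=vol.values > 0.5)


def write_mask(mask: BinaryMask, path) -> None:
    write_volume(ScalarVolume(mask.grid, mask.membership.astype(float)), path)


# ---------------------------------------------------------------------------
# Resolution changes


def downsample(vol: ScalarVolume, target_voxel_mm: float, method: str = "block-mean") -> ScalarVolume:
    """Reduce resolution to ``target_voxel_mm`` by an integer factor.

    ``block-mean`` averages each factor^3 block (mass x voxel-volume is
    conserved); ``subsample`` takes the block-corner voxel. Non-integer
    ratios are rejected so mass accounting stays exact.
    """
    src = vol.grid.voxel_size
    if not np.allclose(src, src[0]):
        raise ValueError("downsample requires isotropic input voxels")
    ratio = target_voxel_mm / src[0]
    factor = int(round(ratio))
    if target_voxel_mm < src[0] - 1e-9:
        raise ValueError("target voxel size smaller than source voxel size")
    if abs(ratio - factor) > 1e-9:
        raise ValueError(f"non-integer downsampling ratio {ratio}")
    if factor == 1:
        return ScalarVolume(vol.grid, vol.values.copy())
    if method not in ("block-mean", "subsample"):
        raise ValueError(f"unknown method {method!r}")

    # pad partial blocks by edge replication so the block mean stays a mean
    shape = np.asarray(vol.grid.shape)
    out_shape = -(-shape // factor)
    pad = out_shape * factor - shape
    values = np.pad(vol.values, [(0, int(p)) for p in pad], mode="edge")
    if method == "block-mean":
        v = values.reshape(
            out_shape[0], factor, out_shape[1], factor, out_shape[2], factor
        )
        out = v.mean(axis=(1, 3, 5))
    else:
        out = values[::factor, ::factor, ::factor]

    # new voxel centres: centre of each block
    new_affine = vol.grid.affine.copy()
    new_affine[:3, :3] *= factor
    centre_shift = vol.grid.affine[:3, :3] @ (np.full(3, (factor - 1) / 2.0))
    new_affine[:3, 3] += centre_shift
    grid = VoxelGrid(shape=tuple(int(s) for s in out_shape), affine=new_affine)
    return ScalarVolume(grid=grid, values=out)
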