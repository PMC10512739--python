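"""3D brain masks and the voxel <-> column-index bijection.

All voxel coordinates are 0-based array indices into a 3D grid; the linear
index of an in-mask voxel is its rank in C (row-major) order over the mask.
Feature matrices throughout the package put voxels in this linear order, so
column ``v`` of a data matrix always refers to ``mask.coords[v]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelMask:
    """In-mask voxel set of a 3D grid with a fixed linear ordering.

    Parameters
    ----------
    shape : tuple of 3 ints
        Grid dimensions.
    coords : (N_V, 3) int array
        In-mask voxel coordinates, sorted in C order. ``coords[v]`` is the
        voxel behind column ``v`` of any data matrix on this mask.
    """

    shape: tuple[int, int, int]
    coords: np.ndarray
    _flat_to_linear: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        coords = np.asarray(self.coords, dtype=np.intp)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N_V, 3) array")
        if coords.size and ((coords < 0).any() or (coords >= np.array(shape)).any()):
            raise ValueError("in-mask coordinates must lie within shape bounds")
        flat = np.ravel_multi_index(coords.T, shape) if coords.size else np.array([], dtype=np.intp)
        if np.unique(flat).size != flat.size:
            raise ValueError("duplicate voxel coordinates in mask")
        order = np.argsort(flat, kind="stable")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "coords", coords[order])
        object.__setattr__(
            self, "_flat_to_linear", {int(f): i for i, f in enumerate(flat[order])}
        )

    @classmethod
    def from_array(cls, mask_array: np.ndarray) -> "VoxelMask":
        """Build from a 3D boolean (or 0/1) array."""
        arr = np.asarray(mask_array)
        if arr.ndim != 3:
            raise ValueError("mask array must be 3D")
        coords = np.argwhere(arr.astype(bool))
        return cls(shape=arr.shape, coords=coords)

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "VoxelMask":
        """Mask covering the whole grid."""
        return cls.from_array(np.ones(shape, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_voxels

    def index_of(self, coord) -> int:
        """Linear index of an in-mask coordinate (KeyError if outside)."""
        flat = int(np.ravel_multi_index(tuple(int(c) for c in coord), self.shape))
        return self._flat_to_linear[flat]

    def contains(self, coord) -> bool:
        try:
            self.index_of(coord)
            return True
        except (KeyError, ValueError):
            return False

    def to_array(self) -> np.ndarray:
        """3D boolean array representation."""
        arr = np.zeros(self.shape, dtype=bool)
        arr[tuple(self.coords.T)] = True
        return arr

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back into a 3D volume (``fill`` outside)."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError("values length must equal number of in-mask voxels")
        vol = np.full(self.shape, fill, dtype=float)
        vol[tuple(self.coords.T)] = values
        return vol
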