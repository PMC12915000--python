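"""Voxel lattices and binary masks.

A :class:`VolumeGrid` fixes the geometry every volume in an analysis shares:
the 3-D array shape, an affine mapping voxel indices to scanner millimetres,
and a brain mask.  A :class:`Mask` is a boolean volume living on a grid.  Both
carry the lexicographic voxel ordering (C order over ``i, j, k``) that maps a
3-D volume to the columns of a pattern matrix, so that every module flattens
voxels the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeGrid:
    """3-D voxel lattice shared by all volumes of a subject.

    Parameters
    ----------
    shape : tuple of 3 ints
        Array dimensions of every volume on this grid.
    voxel_size : float, default 3.0
        Isotropic voxel edge in millimetres.
    affine : (4, 4) array, optional
        Voxel-index to millimetre mapping.  Defaults to a diagonal scaling by
        ``voxel_size`` with the origin at voxel (0, 0, 0).
    brain_mask : bool array, optional
        Voxels considered brain.  Defaults to the full grid.
    """

    shape: tuple
    voxel_size: float = 3.0
    affine: np.ndarray = None
    brain_mask: np.ndarray = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size] * 3 + [1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(self.affine)) < 1e-12:
                raise ValueError("affine must be invertible")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.shape, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.shape:
                raise ValueError("brain_mask shape mismatch")

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the brain mask."""
        return int(self.brain_mask.sum())

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to millimetre coordinates via the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]


@dataclass
class Mask:
    """Boolean region on a :class:`VolumeGrid` (a functional or anatomical ROI)."""

    data: np.ndarray
    grid: VolumeGrid
    name: str = "roi"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        if np.any(self.data & ~self.grid.brain_mask):
            raise ValueError("mask extends outside the brain mask")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n_voxels, 3) voxel indices in fixed lexicographic (C) order."""
        return np.argwhere(self.data)
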