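"""Functional ROI definition and pattern extraction.

ROIs are built the localizer way: threshold a per-subject t-map of a
hand-movement contrast at an uncorrected voxel-level p (one-tailed positive,
activation), optionally drop small connected components, and intersect the
surviving voxels with an anatomical mask.  Patterns handed to the decoders
are raw beta values in a fixed lexicographic voxel order — no scaling or
centering is ever applied here.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .grids import Mask, VolumeGrid

__all__ = [
    "threshold_stat_map",
    "intersect_masks",
    "extract_patterns",
    "embed_patterns",
]

# faces-only connectivity (SPM cluster convention)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def threshold_stat_map(
    tmap: np.ndarray,
    dof: int,
    grid: VolumeGrid,
    p_unc: float = 0.01,
    k_min: int = 0,
    name: str = "functional",
) -> Mask:
    """Threshold a t-statistic map at an uncorrected voxel-level p.

    A voxel survives when its one-tailed (positive) tail probability under a
    t distribution with ``dof`` degrees of freedom is below ``p_unc``;
    6-connected components smaller than ``k_min`` voxels are then removed
    (``k_min = 0`` removes nothing).
    """
    if not (0.0 < p_unc < 1.0):
        raise ValueError("p_unc must lie in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    tmap = np.asarray(tmap, dtype=float)
    if tmap.shape != grid.shape:
        raise ValueError("t-map shape does not match grid")
    t_crit = stats.t.isf(p_unc, dof)
    above = (tmap > t_crit) & grid.brain_mask
    if k_min > 0 and above.any():
        labeled, n = ndimage.label(above, structure=_STRUCT_6)
        sizes = np.bincount(labeled.ravel())
        keep = np.flatnonzero(sizes >= k_min)
        keep = keep[keep != 0]
        above = np.isin(labeled, keep)
    return Mask(data=above, grid=grid, name=name)


def intersect_masks(anatomical: Mask, functional: Mask, name: str | None = None) -> Mask:
    """Voxelwise AND of an anatomical and a functional mask on the same grid."""
    if anatomical.grid.shape != functional.grid.shape or not np.allclose(
        anatomical.grid.affine, functional.grid.affine
    ):
        raise ValueError("masks live on different grids")
    return Mask(
        data=anatomical.data & functional.data,
        grid=anatomical.grid,
        name=name or f"{anatomical.name}&{functional.name}",
    )


def extract_patterns(beta_volumes: np.ndarray, mask: Mask) -> np.ndarray:
    """Flatten beta volumes to a (blocks, voxels) matrix over a mask.

    Voxels are ordered lexicographically by index (C order), the same order
    :func:`embed_patterns` uses; betas are passed through unscaled and
    uncentered.

    Parameters
    ----------
    beta_volumes : array (..., x, y, z)
        Any number of leading axes; they are flattened into the row axis.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    vols = np.asarray(beta_volumes, dtype=float)
    if vols.shape[-3:] != mask.grid.shape:
        raise ValueError("volumes do not live on the mask's grid")
    flat = vols.reshape(-1, *mask.grid.shape)
    patterns = flat[:, mask.data]
    if not np.all(np.isfinite(patterns)):
        raise ValueError("non-finite beta value inside the mask")
    return patterns


def embed_patterns(patterns: np.ndarray, mask: Mask, fill: float = np.nan) -> np.ndarray:
    """Inverse of :func:`extract_patterns`: write pattern columns back into volumes."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[1] != mask.n_voxels:
        raise ValueError("pattern width does not match mask size")
    out = np.full((patterns.shape[0], *mask.grid.shape), fill)
    out[:, mask.data] = patterns
    return out.squeeze()
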