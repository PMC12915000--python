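"""Whole-volume searchlight decoding maps.

A sphere of fixed radius (9 mm by default, 123 voxels on a 3-mm grid when
uncut) is centred on every brain voxel; the decoding scheme is run on the
voxels of the sphere clipped to the brain mask, and the fold-averaged
accuracy is written to the centre voxel.  Centres whose clipped sphere falls
below ``min_voxels`` are skipped (NaN in the map).  Group inference is a
voxelwise one-sample t-test against chance with an uncorrected voxel
threshold and a cluster-extent rule; searchlight permutation testing is
deliberately not offered (its cost dwarfs its value next to the ROI tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import decode
from .grids import VolumeGrid

__all__ = [
    "SearchlightSpec",
    "sphere_offsets",
    "run_searchlight",
    "group_cluster_report",
]


@dataclass(frozen=True)
class SearchlightSpec:
    """Geometry and floor of the moving sphere."""

    radius_mm: float = 9.0
    voxel_mm: float = 3.0
    min_voxels: int = 100
    scheme: str = "within-exec"

    def __post_init__(self):
        if self.radius_mm < self.voxel_mm:
            raise ValueError("radius must be at least one voxel")
        full = len(sphere_offsets(self.radius_mm, self.voxel_mm))
        if self.min_voxels > full:
            raise ValueError(
                f"min_voxels={self.min_voxels} exceeds the full sphere ({full})"
            )


def sphere_offsets(radius_mm: float, voxel_mm: float) -> np.ndarray:
    """Integer voxel offsets within ``radius_mm`` of the centre (origin included)."""
    if radius_mm <= 0 or voxel_mm <= 0:
        raise ValueError("radius and voxel size must be positive")
    r = int(np.floor(radius_mm / voxel_mm))
    axis = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    offs = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    keep = (offs**2).sum(axis=1) * voxel_mm**2 <= radius_mm**2 + 1e-9
    return offs[keep]


@dataclass
class _SphereDataset:
    """Adapter exposing sphere-restricted patterns to the decode schemes."""

    betas: np.ndarray      # modality x session x block x voxel
    labels: np.ndarray
    n_sessions: int
    subject_id: str = "searchlight"


def _as_modality_first(volumes: np.ndarray, labels: np.ndarray):
    volumes = np.asarray(volumes, dtype=float)
    labels = np.asarray(labels)
    if volumes.ndim == 5:        # single modality: sessions x blocks x (x,y,z)
        volumes = volumes[None]
        labels = labels[None]
    if volumes.ndim != 6:
        raise ValueError("volumes must be (sessions, blocks, x, y, z) "
                         "or (modalities, sessions, blocks, x, y, z)")
    return volumes, labels


def run_searchlight(
    volumes: np.ndarray,
    labels: np.ndarray,
    grid: VolumeGrid,
    spec: SearchlightSpec = SearchlightSpec(),
) -> np.ndarray:
    """Sweep the searchlight sphere over the brain mask.

    Parameters
    ----------
    volumes : array, (sessions, blocks, x, y, z) or with a leading modality axis
        Block-level beta volumes.  Single-modality input runs the within
        scheme on that modality regardless of the spec's modality tag.
    labels : matching (sessions, blocks) or (modalities, sessions, blocks)
        Finger label of each block.
    grid : VolumeGrid
        Supplies the brain mask (centres and sphere clipping) and geometry.

    Returns
    -------
    3-D accuracy map in percent; NaN at skipped or non-brain voxels.
    """
    volumes, labels = _as_modality_first(volumes, labels)
    if not grid.brain_mask.any():
        raise ValueError("brain mask is empty")
    shape = grid.shape
    if volumes.shape[-3:] != shape:
        raise ValueError("volumes do not live on the grid")
    n_mod, S, B = volumes.shape[:3]
    if n_mod == 1:
        scheme = decode.make_scheme("within-exec", S)
        betas_full = np.concatenate([volumes, volumes], axis=0)
        labels_full = np.concatenate([labels, labels], axis=0)
    else:
        scheme = decode.make_scheme(spec.scheme, S)
        betas_full, labels_full = volumes, labels
    flat = betas_full.reshape(2, S, B, -1)

    offs = sphere_offsets(spec.radius_mm, spec.voxel_mm)
    mask_flat = grid.brain_mask.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    acc_map = np.full(shape, np.nan)
    centers = np.argwhere(grid.brain_mask)
    for c in centers:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        lin = pts[ok] @ strides
        lin = lin[mask_flat[lin]]
        if lin.size < spec.min_voxels:
            continue
        ds = _SphereDataset(
            betas=flat[..., lin], labels=labels_full, n_sessions=S
        )
        rec = decode.run_scheme(ds, scheme)
        acc_map[tuple(c)] = rec.accuracy
    return acc_map


def group_cluster_report(
    maps,
    chance: float,
    grid: VolumeGrid,
    p_thresh: float = 0.0005,
    k_min: int = 10,
) -> pd.DataFrame:
    """Cluster table of voxels where group accuracy exceeds chance.

    One-sample t-test (one-tailed, accuracy > chance) at each voxel where
    every subject has a value, thresholded at uncorrected ``p_thresh``;
    surviving voxels are grouped into 6-connected clusters and clusters
    smaller than ``k_min`` voxels are dropped.

    Returns a table with one row per cluster: size, peak t, peak voxel
    indices and peak millimetre coordinates.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4 or maps.shape[0] < 2:
        raise ValueError("need at least two aligned subject maps")
    if maps.shape[1:] != grid.shape:
        raise ValueError("maps do not live on the grid")
    valid = np.all(np.isfinite(maps), axis=0)
    tmap = np.full(grid.shape, -np.inf)
    if valid.any():
        vals = maps[:, valid]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        n = maps.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean - chance) / (sd / np.sqrt(n))
        t[~np.isfinite(t)] = -np.inf
        tmap[valid] = t
    t_crit = stats.t.isf(p_thresh, maps.shape[0] - 1)
    above = tmap > t_crit
    labeled, n_clusters = ndimage.label(
        above, structure=ndimage.generate_binary_structure(3, 1)
    )
    rows = []
    for cid in range(1, n_clusters + 1):
        sel = labeled == cid
        size = int(sel.sum())
        if size < k_min:
            continue
        masked_t = np.where(sel, tmap, -np.inf)
        peak = np.unravel_index(np.argmax(masked_t), grid.shape)
        mm = grid.voxel_to_mm(np.array([peak]))[0]
        rows.append(
            {
                "n_voxels": size,
                "peak_t": float(tmap[peak]),
                "i": peak[0], "j": peak[1], "k": peak[2],
                "x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
            }
        )
    df = pd.DataFrame(
        rows, columns=["n_voxels", "peak_t", "i", "j", "k", "x_mm", "y_mm", "z_mm"]
    )
    return df.sort_values("peak_t", ascending=False, ignore_index=True) if len(df) else df
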