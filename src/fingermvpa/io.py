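"""NIfTI-1 and table input/output.

Beta images travel as 4-D NIfTI (one volume per block regressor), masks as
3-D NIfTI with integer data, block tables as TSV with the columns
(modality, session, block, finger, onset_s, duration_s).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import Mask, VolumeGrid

BLOCK_TABLE_COLUMNS = ["modality", "session", "block", "finger", "onset_s", "duration_s"]


def save_beta_image(volumes: np.ndarray, grid: VolumeGrid, path) -> None:
    """Write block-beta volumes as 4-D NIfTI-1 (last axis = block)."""
    vols = np.asarray(volumes, dtype=np.float64)
    vols4d = np.moveaxis(vols.reshape(-1, *grid.shape), 0, -1)
    nib.save(nib.Nifti1Image(vols4d, grid.affine), str(path))


def load_beta_image(path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a 4-D beta image; returns (blocks, x, y, z) data and its grid."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    grid = VolumeGrid(
        shape=data.shape[:3],
        voxel_size=float(np.abs(img.affine[0, 0])) or 3.0,
        affine=img.affine,
    )
    return np.moveaxis(data, -1, 0), grid


def save_mask(mask: Mask, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine), str(path)
    )


def load_mask(path, grid: VolumeGrid | None = None, name: str | None = None) -> Mask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata()) > 0.5
    if grid is None:
        grid = VolumeGrid(
            shape=data.shape,
            voxel_size=float(np.abs(img.affine[0, 0])) or 3.0,
            affine=img.affine,
            brain_mask=data.copy(),
        )
    return Mask(data=data, grid=grid, name=name or Path(str(path)).stem)


def save_block_table(table: pd.DataFrame, path) -> None:
    table[BLOCK_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def load_block_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(BLOCK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"block table misses columns: {sorted(missing)}")
    return table


def save_rdm_csv(rdm, path) -> None:
    rdm.frame().to_csv(path)


def load_rdm_csv(path):
    from .rsa import RDM

    frame = pd.read_csv(path, index_col=0)
    return RDM(D=frame.to_numpy(), conditions=tuple(frame.columns))
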