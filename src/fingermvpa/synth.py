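"""Synthetic subjects with a shared, scaled-down finger code.

The generator emulates a two-modality finger-tapping experiment: four fingers
of the right hand, each executed and kinesthetically imagined, 4 sessions per
modality with 12 task blocks per session (3 per finger).  Each subject owns
four latent finger patterns ``v_f`` over ROI voxels; a block-level beta
pattern is

    execution:  a_E * v_f + m * u_E + eps
    imagery:    s * a_E * v_f + m * u_I + eps'

so imagery reuses the execution finger code at a reduced amplitude ``s``
(the "scaled-down" shared representation), while a finger-independent
modality offset ``m * u`` gives a between-modality classifier something real
to find.  Neighbouring fingers are correlated (somatotopic overlap) by
convolving the latent patterns along the finger axis; noise is spatially
correlated across voxels with an AR(1) profile whose true covariance is kept
on the dataset so whitening can be validated.

Everything is driven by one integer seed and is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import Mask, VolumeGrid

__all__ = [
    "SynthConfig",
    "SubjectDataset",
    "SearchlightVolume",
    "generate_subject",
    "generate_timeseries",
    "generate_searchlight_volume",
    "default_block_table",
    "MODALITIES",
    "FINGERS",
]

MODALITIES = ("execution", "imagery")
FINGERS = ("index", "middle", "ring", "little")

#: scans retained per task session (100 acquired, first two discarded)
N_SCANS = 98
TR_S = 3.0
BLOCK_DURATION_S = 12.0


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one synthetic subject.

    Parameters
    ----------
    n_voxels : int
        ROI size; the default 370 matches the mean hand-area M1 ROI size the
        pipeline is meant to emulate.
    n_sessions_per_modality, n_blocks_per_session : int
        4 sessions x 12 blocks (3 per finger) per modality.
    exec_amplitude : float
        Amplitude ``a_E`` of the execution finger patterns, in beta units.
    imagery_scale : float in [0, 1]
        Shared-code scale ``s``: imagery finger pattern is ``s * a_E * v_f``.
        ``s = 0`` removes all cross-modal finger information.
    modality_offset_amplitude : float
        Amplitude ``m`` of a finger-independent offset, constant within each
        modality (a fixed random unit vector per subject and modality).
    finger_adjacency : float in [0, 1)
        Correlation injected between neighbouring-finger patterns by
        convolving the latent patterns along the finger axis with the kernel
        ``[rho/2, 1, rho/2]`` and rescaling to unit voxel variance.
    noise_sd : float
        Per-voxel noise standard deviation of execution blocks.
    noise_sd_imagery : float
        Noise SD of imagery blocks; the default exceeds ``noise_sd`` because
        imagined movements produce noisier, weaker patterns than executed
        ones, which also reproduces the empirical asymmetry that decoders
        trained on imagery and tested on execution outperform the reverse.
    noise_spatial_corr : float in [0, 1)
        Lag-1 coefficient of the AR(1) spatial noise profile
        ``cov(eps_i, eps_j) = sd^2 * phi^|i-j|`` over the voxel ordering.
    imagery_jitter : float
        Optional SD of an imagery-specific perturbation of the finger
        patterns (0 keeps the shared code exact, the cleanest ground truth).
    """

    n_voxels: int = 370
    n_sessions_per_modality: int = 4
    n_blocks_per_session: int = 12
    exec_amplitude: float = 1.0
    imagery_scale: float = 0.3
    modality_offset_amplitude: float = 15.0
    finger_adjacency: float = 0.4
    noise_sd: float = 4.0
    noise_sd_imagery: float = 6.0
    noise_spatial_corr: float = 0.3
    imagery_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")
        if self.noise_sd <= 0 or self.noise_sd_imagery <= 0:
            raise ValueError("noise SDs must be positive")
        if not (0.0 <= self.imagery_scale <= 1.0):
            raise ValueError("imagery_scale must lie in [0, 1]")
        if not (0.0 <= self.finger_adjacency < 1.0):
            raise ValueError("finger_adjacency must lie in [0, 1)")
        if not (0.0 <= self.noise_spatial_corr < 1.0):
            raise ValueError("noise_spatial_corr must lie in [0, 1)")
        if self.exec_amplitude < 0 or self.modality_offset_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_blocks_per_session % len(FINGERS) != 0:
            raise ValueError("n_blocks_per_session must be a multiple of 4")


@dataclass
class SubjectDataset:
    """All block-level beta patterns of one subject.

    ``betas`` is indexed ``[modality, session, block, voxel]`` with modality 0
    = execution, 1 = imagery; ``labels`` holds the finger index (1-4) of each
    block.  ``truth`` retains the generating quantities (finger patterns,
    modality offsets, true noise covariance) for recovery tests and is only
    present on synthetic data.
    """

    betas: np.ndarray
    labels: np.ndarray
    grid: VolumeGrid
    roi: Mask
    truth: dict | None = None
    subject_id: str = "synth"

    def __post_init__(self):
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")
        # uniform finger histogram per session
        n_per = self.labels.shape[-1] // len(FINGERS)
        for mod in range(self.labels.shape[0]):
            for ses in range(self.labels.shape[1]):
                counts = np.bincount(self.labels[mod, ses], minlength=5)[1:]
                if not np.all(counts == n_per):
                    raise ValueError("finger labels are not balanced within a session")

    @property
    def n_sessions(self) -> int:
        return self.betas.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[-1]

    def patterns(self, modality: int) -> np.ndarray:
        """(n_sessions, n_blocks, n_voxels) betas of one modality."""
        return self.betas[modality]

    def condition_means(self, modality: int) -> np.ndarray:
        """Session-wise condition patterns: mean of the same-finger blocks.

        Returns an array (n_sessions, 4, n_voxels) in finger order 1..4.
        """
        out = np.empty((self.n_sessions, len(FINGERS), self.n_voxels))
        for ses in range(self.n_sessions):
            for f in range(len(FINGERS)):
                sel = self.labels[modality, ses] == f + 1
                out[ses, f] = self.betas[modality, ses, sel].mean(axis=0)
        return out

    def block_table(self) -> pd.DataFrame:
        """Long-format table (modality, session, block, finger, onset, duration)."""
        rows = []
        for mod in range(2):
            for ses in range(self.betas.shape[1]):
                onsets = _default_onsets(self.betas.shape[2])
                for blk in range(self.betas.shape[2]):
                    rows.append(
                        {
                            "modality": MODALITIES[mod],
                            "session": ses + 1,
                            "block": blk + 1,
                            "finger": int(self.labels[mod, ses, blk]),
                            "onset_s": onsets[blk],
                            "duration_s": BLOCK_DURATION_S,
                        }
                    )
        return pd.DataFrame(rows)


def _roi_grid(n_voxels: int) -> tuple[VolumeGrid, Mask]:
    """Compact cubic grid holding ``n_voxels`` ROI voxels in C order."""
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    shape = (side, side, side)
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    flat[:n_voxels] = True
    mask_data = flat.reshape(shape)
    grid = VolumeGrid(shape=shape, voxel_size=3.0, brain_mask=mask_data.copy())
    return grid, Mask(data=mask_data, grid=grid, name="synthetic-roi")


def _finger_patterns(rng: np.random.Generator, n_voxels: int, rho: float) -> np.ndarray:
    """Latent finger patterns with neighbour correlation about ``rho``.

    Independent standard-normal patterns are convolved along the finger axis
    with ``[rho/2, 1, rho/2]`` (truncated at the edges) and rescaled to unit
    voxel variance, which leaves neighbouring fingers correlated and
    next-neighbours correlated at second order.
    """
    raw = rng.standard_normal((len(FINGERS), n_voxels))
    if rho == 0.0:
        return raw
    mixed = raw.copy()
    mixed[:-1] += 0.5 * rho * raw[1:]
    mixed[1:] += 0.5 * rho * raw[:-1]
    return mixed / np.sqrt((mixed**2).mean(axis=1, keepdims=True))


def _ar1_noise(
    rng: np.random.Generator, shape: tuple, sd: float, phi: float
) -> np.ndarray:
    """Zero-mean noise, unit-free AR(1) spatial correlation along the last axis."""
    z = rng.standard_normal(shape)
    if phi == 0.0:
        return sd * z
    out = np.empty_like(z)
    out[..., 0] = z[..., 0]
    scale = np.sqrt(1.0 - phi**2)
    for v in range(1, shape[-1]):
        out[..., v] = phi * out[..., v - 1] + scale * z[..., v]
    return sd * out


def ar1_covariance(n_voxels: int, sd: float, phi: float) -> np.ndarray:
    """True noise covariance sd^2 * phi^|i-j| of the AR(1) spatial profile."""
    idx = np.arange(n_voxels)
    return sd**2 * phi ** np.abs(idx[:, None] - idx[None, :])


def _session_labels(rng: np.random.Generator, n_blocks: int) -> np.ndarray:
    per = n_blocks // len(FINGERS)
    labels = np.repeat(np.arange(1, len(FINGERS) + 1), per)
    return rng.permutation(labels)


def _default_onsets(n_blocks: int) -> np.ndarray:
    # 6 s lead-in, then 12 s task + 12 s non-task per block cycle
    return 6.0 + 24.0 * np.arange(n_blocks)


def default_block_table(labels: np.ndarray, modality: str = "execution",
                        session: int = 1) -> pd.DataFrame:
    """Session block table on the task timing grid (12-s blocks, 24-s cycle)."""
    onsets = _default_onsets(len(labels))
    return pd.DataFrame(
        {
            "modality": modality,
            "session": session,
            "block": np.arange(1, len(labels) + 1),
            "finger": np.asarray(labels, dtype=int),
            "onset_s": onsets,
            "duration_s": BLOCK_DURATION_S,
        }
    )


def generate_subject(cfg: SynthConfig, rng: np.random.Generator | None = None) -> SubjectDataset:
    """Draw one synthetic subject's block-level beta patterns.

    Deterministic for a fixed config seed (or a supplied generator); distinct
    seeds give independent subjects.  The generating finger patterns,
    modality offsets and true noise covariance are retained in ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    P = cfg.n_voxels
    v = _finger_patterns(rng, P, cfg.finger_adjacency)
    u_exec = rng.standard_normal(P)
    u_exec /= np.linalg.norm(u_exec)
    u_imag = rng.standard_normal(P)
    u_imag /= np.linalg.norm(u_imag)
    v_imag = v
    if cfg.imagery_jitter > 0:
        v_imag = v + cfg.imagery_jitter * rng.standard_normal(v.shape)

    S, B = cfg.n_sessions_per_modality, cfg.n_blocks_per_session
    labels = np.empty((2, S, B), dtype=int)
    betas = np.empty((2, S, B, P))
    for mod, (amp, pat, offset, sd) in enumerate(
        [
            (cfg.exec_amplitude, v, u_exec, cfg.noise_sd),
            (cfg.imagery_scale * cfg.exec_amplitude, v_imag, u_imag, cfg.noise_sd_imagery),
        ]
    ):
        for ses in range(S):
            labels[mod, ses] = _session_labels(rng, B)
            noise = _ar1_noise(rng, (B, P), sd, cfg.noise_spatial_corr)
            signal = amp * pat[labels[mod, ses] - 1]
            betas[mod, ses] = signal + cfg.modality_offset_amplitude * offset + noise

    grid, roi = _roi_grid(P)
    truth = {
        "finger_patterns": v,
        "finger_patterns_imagery": v_imag,
        "offset_execution": u_exec,
        "offset_imagery": u_imag,
        "noise_cov_execution": ar1_covariance(P, cfg.noise_sd, cfg.noise_spatial_corr),
        "noise_cov_imagery": ar1_covariance(P, cfg.noise_sd_imagery, cfg.noise_spatial_corr),
        "config": cfg,
    }
    return SubjectDataset(
        betas=betas, labels=labels, grid=grid, roi=roi, truth=truth,
        subject_id=f"synth-{cfg.seed}",
    )


def generate_timeseries(
    cfg: SynthConfig,
    block_table: pd.DataFrame,
    betas_true: np.ndarray,
    n_scans: int = N_SCANS,
    tr: float = TR_S,
    noise_sd: float | None = None,
    drift_amplitude: float = 0.0,
    baseline: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward BOLD model: Y = X_task @ B + baseline + drift + white noise.

    The task design (boxcars convolved with the canonical HRF, sampled at TR)
    comes from :func:`fingermvpa.glm.build_design`; drift is a random-phase
    cosine with period drawn above the 128-s high-pass cutoff, so a correctly
    specified GLM absorbs it in the drift columns.

    Parameters
    ----------
    block_table : DataFrame with onset_s / duration_s columns
    betas_true : (n_blocks, n_voxels) amplitudes of each block regressor.
    noise_sd : float, optional
        Scan-level white-noise SD; defaults to the config's ``noise_sd``.
    """
    from .glm import DesignError, build_design

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    betas_true = np.atleast_2d(np.asarray(betas_true, dtype=float))
    if len(block_table) != betas_true.shape[0]:
        raise DesignError("one beta row per block is required")
    design = build_design(block_table, n_scans=n_scans, tr=tr)
    X_task = design.X[:, design.task_columns]
    Y = X_task @ betas_true + baseline
    if drift_amplitude > 0:
        period = rng.uniform(150.0, 2 * n_scans * tr)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_scans) * tr
        drift = drift_amplitude * np.cos(2 * np.pi * t / period + phase)
        Y = Y + drift[:, None]
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        Y = Y + sd * rng.standard_normal(Y.shape)
    return Y


@dataclass
class SearchlightVolume:
    """4-D beta volumes with finger signal confined to a planted sphere."""

    betas: np.ndarray          # sessions x blocks x (x, y, z)
    labels: np.ndarray         # sessions x blocks, finger 1-4
    grid: VolumeGrid
    signal_center: tuple
    signal_radius_mm: float


def generate_searchlight_volume(
    cfg: SynthConfig,
    grid_shape: tuple,
    signal_center: tuple,
    signal_radius_mm: float,
    rng: np.random.Generator | None = None,
) -> SearchlightVolume:
    """Whole-volume fixture for searchlight mapping.

    Finger-specific signal (amplitude ``exec_amplitude``) is planted only in
    the voxels within ``signal_radius_mm`` of ``signal_center``; everywhere
    else the betas are label-independent noise, so a correct searchlight map
    is at chance outside the planted sphere.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    grid = VolumeGrid(shape=grid_shape, voxel_size=3.0)
    center = np.asarray(signal_center, dtype=float)
    ijk = np.indices(grid_shape).reshape(3, -1).T
    dist_mm = np.linalg.norm((ijk - center) * grid.voxel_size, axis=1)
    inside = dist_mm <= signal_radius_mm
    if not inside.any():
        raise ValueError("signal sphere contains no voxels")
    if np.any(center * grid.voxel_size - signal_radius_mm < -1e-9) or np.any(
        (center - np.array(grid_shape) + 1) * grid.voxel_size + signal_radius_mm > 1e-9
    ):
        raise ValueError("signal sphere does not fit inside the grid")

    n_signal = int(inside.sum())
    v = _finger_patterns(rng, n_signal, cfg.finger_adjacency)
    S, B = cfg.n_sessions_per_modality, cfg.n_blocks_per_session
    P = int(np.prod(grid_shape))
    labels = np.empty((S, B), dtype=int)
    flat = np.empty((S, B, P))
    for ses in range(S):
        labels[ses] = _session_labels(rng, B)
        flat[ses] = cfg.noise_sd * rng.standard_normal((B, P))
        flat[ses][:, inside] += cfg.exec_amplitude * v[labels[ses] - 1]
    return SearchlightVolume(
        betas=flat.reshape(S, B, *grid_shape),
        labels=labels,
        grid=grid,
        signal_center=tuple(signal_center),
        signal_radius_mm=float(signal_radius_mm),
    )
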