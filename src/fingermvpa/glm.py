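"""Block-design GLM: canonical HRF, design construction, beta estimation.

Each 12-s task block gets its own boxcar regressor, convolved with the
canonical double-gamma hemodynamic response function and sampled on the TR
grid.  Low-frequency scanner drift is modelled with a discrete-cosine basis
whose slowest retained period is the high-pass cutoff (128 s by default), so
degrees of freedom stay explicit instead of being absorbed by filtering the
data.  Betas are ordinary least squares; an optional AR(1) prewhitening pass
(global lag-1 coefficient pooled over voxels) is available for time series
with serial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "DesignMatrix",
    "BetaEstimates",
    "canonical_hrf",
    "build_design",
    "fit_betas",
    "DesignError",
]


class DesignError(ValueError):
    """Raised for invalid block tables (overlaps, blocks beyond the scan window)."""


@dataclass
class DesignMatrix:
    """Per-session regressor matrix.

    Attributes
    ----------
    X : (n_scans, n_regressors) array
    names : list of str
        Column names: task columns first (``task_01`` ...), then drift
        columns (``drift_1`` ...), then ``intercept``.
    tr : float
        Repetition time in seconds.
    """

    X: np.ndarray
    names: list
    tr: float

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X columns must match names")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def task_columns(self) -> list:
        return [i for i, n in enumerate(self.names) if n.startswith("task_")]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)


@dataclass
class BetaEstimates:
    """OLS (optionally prewhitened) parameter estimates for one session."""

    B: np.ndarray            # regressors x voxels
    residuals: np.ndarray    # scans x voxels
    dof: int
    names: list
    ar_rho: float = 0.0      # 0.0 means no prewhitening applied

    def task_betas(self) -> np.ndarray:
        """(n_task_blocks, n_voxels) betas of the task regressors only."""
        idx = [i for i, n in enumerate(self.names) if n.startswith("task_")]
        return self.B[idx]

    def intercept_beta(self) -> np.ndarray:
        return self.B[self.names.index("intercept")]


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a grid of step ``dt`` seconds.

    The kernel is the difference of two gamma densities — response peaking at
    6 s and an undershoot peaking at 16 s with one sixth the amplitude, both
    with unit dispersion — truncated at 32 s and scaled so its maximum is 1.

    Parameters
    ----------
    dt : float
        Sampling step in seconds (must be positive).
    duration : float
        Kernel length in seconds.

    Returns
    -------
    ndarray of shape (floor(duration/dt) + 1,)
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)

    def gamma_pdf(t, mode):
        # unit-dispersion gamma density with its mode at `mode`: shape = mode + 1
        shape = mode + 1.0
        with np.errstate(divide="ignore"):
            logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
        return np.where(t > 0, np.exp((shape - 1) * logt - t - gammaln(shape)), 0.0)

    h = gamma_pdf(t, 6.0) - gamma_pdf(t, 16.0) / 6.0
    return h / h.max()


def _dct_drift_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift columns with periods longer than ``cutoff`` seconds.

    Column k has period 2*n_scans*tr/k; all k with period strictly longer
    than the cutoff are retained, i.e. K = floor(2*n_scans*tr/cutoff) columns
    (one fewer on an exact multiple).  The constant term is excluded — the
    intercept covers it.
    """
    total = 2.0 * n_scans * tr / cutoff
    K = int(np.floor(total)) - (1 if np.isclose(total, np.round(total)) else 0)
    i = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * i + 1) / (2.0 * n_scans))
        for k in range(1, K + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def build_design(
    block_table: pd.DataFrame,
    n_scans: int,
    tr: float = 3.0,
    cutoff: float = 128.0,
    microtime_dt: float = 0.1,
) -> DesignMatrix:
    """Build a session design matrix from a block table.

    Parameters
    ----------
    block_table : DataFrame with columns ``onset_s`` and ``duration_s``
        One row per task block.  Each block becomes its own regressor: a
        boxcar on a fine time grid (``microtime_dt`` resolution) convolved
        with the canonical HRF and sampled at scan acquisition times
        ``i * tr``.
    n_scans : int
        Retained scans in the session.
    tr : float
        Repetition time (s).
    cutoff : float
        High-pass cutoff period (s); cosine drift regressors with longer
        periods are appended.

    Raises
    ------
    DesignError
        If blocks overlap or run past the scan window.
    """
    onsets = np.asarray(block_table["onset_s"], dtype=float)
    durs = np.asarray(block_table["duration_s"], dtype=float)
    order = np.argsort(onsets)
    t_end = n_scans * tr
    for a, b in zip(order[:-1], order[1:]):
        if onsets[a] + durs[a] > onsets[b] + 1e-9:
            raise DesignError(
                f"blocks at {onsets[a]:.1f}s and {onsets[b]:.1f}s overlap"
            )
    if len(onsets) and (onsets + durs).max() > t_end + 1e-9:
        raise DesignError("a block overruns the scan window")

    n_fine = int(np.ceil(t_end / microtime_dt)) + 1
    t_fine = np.arange(n_fine) * microtime_dt
    hrf = canonical_hrf(microtime_dt)
    scan_idx = np.round(np.arange(n_scans) * tr / microtime_dt).astype(int)

    cols, names = [], []
    for j, (on, du) in enumerate(zip(onsets, durs)):
        box = ((t_fine >= on - 1e-9) & (t_fine < on + du - 1e-9)).astype(float)
        conv = np.convolve(box, hrf)[:n_fine]
        cols.append(conv[scan_idx])
        names.append(f"task_{j + 1:02d}")

    drift = _dct_drift_basis(n_scans, tr, cutoff)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_scans))
    names.append("intercept")

    X = np.column_stack(cols)
    for j in range(len(onsets)):
        if not np.any(X[:, j]):
            raise DesignError(f"task column {j} is all zero")
    return DesignMatrix(X=X, names=names, tr=tr)


def _estimate_ar1(residuals: np.ndarray) -> float:
    """Global lag-1 autocorrelation pooled over voxels."""
    r0, r1 = residuals[:-1], residuals[1:]
    denom = np.sum(r0 * r0)
    return float(np.sum(r0 * r1) / denom) if denom > 0 else 0.0


def fit_betas(
    Y: np.ndarray,
    design: DesignMatrix,
    ar1: bool = False,
    allow_rank_deficient: bool = False,
) -> BetaEstimates:
    """Estimate betas by OLS, optionally with two-pass AR(1) prewhitening.

    Parameters
    ----------
    Y : (n_scans, n_voxels) array
    design : DesignMatrix
    ar1 : bool
        When True, fit OLS once, estimate a single AR(1) coefficient from the
        pooled residuals, prewhiten both sides and refit.
    allow_rank_deficient : bool
        Permit a rank-deficient design (pseudo-inverse solution, with a
        warning); otherwise this is an error.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] != design.n_scans and Y.shape[1] == design.n_scans:
        raise ValueError("Y must be scans x voxels")
    if Y.shape[0] != design.n_scans:
        raise ValueError(
            f"Y has {Y.shape[0]} scans but the design expects {design.n_scans}"
        )
    X = design.X
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if not allow_rank_deficient:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient; pass allow_rank_deficient=True"
            )
        warnings.warn("rank-deficient design: using pseudo-inverse", RuntimeWarning)

    def ols(Xw, Yw):
        B, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        return B, Yw - Xw @ B

    B, resid = ols(X, Y)
    rho = 0.0
    if ar1:
        rho = _estimate_ar1(resid)
        Xw = X.copy()
        Yw = Y.copy()
        Xw[1:] -= rho * X[:-1]
        Yw[1:] -= rho * Y[:-1]
        Xw[0] *= np.sqrt(1 - rho**2)
        Yw[0] *= np.sqrt(1 - rho**2)
        B, _ = ols(Xw, Yw)
        resid = Y - X @ B
    dof = design.n_scans - rank
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    return BetaEstimates(B=B, residuals=resid, dof=int(dof), names=list(design.names), ar_rho=rho)
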