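"""Representational similarity analysis with crossnobis distances.

The representational dissimilarity matrix (RDM) covers the 8 conditions
{execution, imagery} x {index, middle, ring, little} — 64 condition pairs.
Dissimilarity is the cross-validated Mahalanobis (crossnobis) distance:
pattern differences from two independent data partitions are multiplied
through the inverse noise covariance, so the distance is unbiased — its
expectation is zero when two conditions do not differ, and estimates may
legitimately be negative (the naive Mahalanobis distance, computed from a
single partition, is positively biased; both are provided so the gap can be
measured).

Partitioning follows a leave-one-session-pair-out rule: fold k puts session
k of the execution task and session k of the imagery task on one side and
the remaining three sessions of each task on the other, giving four folds
whose distances are averaged.  The voxel noise covariance is estimated from
within-condition beta residuals with shrinkage toward its diagonal; the
fixed shrinkage coefficient 0.4 is the default (a value that behaves well on
fMRI patterns where the sample covariance is ill-conditioned), with an
optimal analytic shrinkage estimator available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .synth import FINGERS, SubjectDataset

__all__ = [
    "RDM",
    "NoiseCov",
    "CONDITIONS",
    "FINGER_PAIRS",
    "shrinkage_covariance",
    "crossnobis_distances",
    "crossnobis_rdm",
    "naive_mahalanobis_rdm",
    "diag_offdiag_contrast",
    "within_task_pair_table",
    "classical_mds",
]

# digit numbering: the index finger is digit 2
CONDITIONS = ("E2", "E3", "E4", "E5", "I2", "I3", "I4", "I5")

#: the six unordered finger pairs, adjacent pairs first
FINGER_PAIRS = (
    ("index", "middle"), ("middle", "ring"), ("ring", "little"),
    ("index", "ring"), ("middle", "little"), ("index", "little"),
)


@dataclass
class RDM:
    """8x8 symmetric crossnobis dissimilarity matrix (zero diagonal)."""

    D: np.ndarray
    conditions: tuple = CONDITIONS
    subject: str = "subject"

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.conditions),) * 2:
            raise ValueError("RDM must be square over the conditions")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")

    def cross_block(self) -> np.ndarray:
        """4x4 execution-vs-imagery block (rows: executed finger, cols: imagined)."""
        return self.D[:4, 4:]

    def within_task(self, task: str) -> np.ndarray:
        sl = slice(0, 4) if task == "execution" else slice(4, 8)
        return self.D[sl, sl]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.conditions, columns=self.conditions)


@dataclass
class NoiseCov:
    """Shrunk voxel-by-voxel noise covariance."""

    sigma: np.ndarray
    lam: float
    source: str              # "optimal" | "fixed-0.4" | explicit
    jittered: bool = False


def _shrink(S: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * S + lam * np.diag(np.diag(S))


def _optimal_lambda(residuals: np.ndarray, S: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the diagonal target.

    Ratio of the summed sampling variances of the off-diagonal covariance
    entries to their summed squares, clipped to [0, 1].
    """
    n = residuals.shape[0]
    X = residuals - residuals.mean(axis=0)
    # w_k(i,j) = x_ki * x_kj ; Var(s_ij) ~ n/(n-1)^3 * sum_k (w_k - w_bar)^2
    W2_sum = (X**2).T @ (X**2)                # sum_k w_k^2
    W_sum = X.T @ X                           # sum_k w_k
    var_s = n / (n - 1.0) ** 3 * (W2_sum - W_sum**2 / n)
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = np.sum(S[off] ** 2)
    if denom <= 0:
        return 1.0
    return float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))


def shrinkage_covariance(residuals: np.ndarray, mode="fixed") -> NoiseCov:
    """Estimate the voxel noise covariance with diagonal shrinkage.

    Parameters
    ----------
    residuals : (n_obs, n_voxels) array
        Within-condition beta residuals or GLM scan residuals.
    mode : "fixed" (lambda = 0.4), "optimal", or a float in [0, 1]
        Shrinkage intensity; the shrunk matrix is
        ``(1 - lambda) * S + lambda * diag(S)``.

    The result is guaranteed symmetric positive definite (a small diagonal
    jitter is added in the degenerate case and flagged).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ValueError("need at least two residual observations")
    S = np.cov(residuals, rowvar=False)
    S = np.atleast_2d(S)
    if mode == "fixed":
        lam, source = 0.4, "fixed-0.4"
    elif mode == "optimal":
        lam, source = _optimal_lambda(residuals, S), "optimal"
    else:
        lam = float(mode)
        if not (0.0 <= lam <= 1.0):
            raise ValueError("shrinkage coefficient must lie in [0, 1]")
        source = f"fixed-{lam}"
    sigma = _shrink(S, lam)
    jittered = False
    try:
        linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        eps = 1e-10 * max(np.trace(sigma) / sigma.shape[0], 1.0)
        while True:
            try:
                linalg.cholesky(sigma + eps * np.eye(sigma.shape[0]), lower=True)
                break
            except linalg.LinAlgError:
                eps *= 10
        sigma = sigma + eps * np.eye(sigma.shape[0])
        jittered = True
        warnings.warn("noise covariance required diagonal jitter", RuntimeWarning)
    return NoiseCov(sigma=sigma, lam=lam, source=source, jittered=jittered)


def crossnobis_distances(
    A: np.ndarray,
    B: np.ndarray,
    sigma_inv: np.ndarray | None = None,
    n_norm: int | None = None,
) -> np.ndarray:
    """Cross-validated squared Mahalanobis distances between condition sets.

    ``A`` and ``B`` are (n_conditions, n_voxels) pattern estimates from two
    independent partitions; the returned matrix has entries

        d(i, j) = (a_i - a_j)' Sigma^-1 (b_i - b_j) / n_norm

    (identity whitening when ``sigma_inv`` is None; no normalization when
    ``n_norm`` is None).  Symmetric with an exactly zero diagonal.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape != B.shape:
        raise ValueError("partitions must contain the same conditions")
    dA = A[:, None, :] - A[None, :, :]
    dB = B[:, None, :] - B[None, :, :]
    if sigma_inv is None:
        D = np.einsum("ijv,ijv->ij", dA, dB)
    else:
        D = np.einsum("ijv,vw,ijw->ij", dA, sigma_inv, dB)
    if n_norm:
        D = D / n_norm
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def _condition_means_for_sessions(dataset, modality, sessions):
    """(4, n_voxels) finger patterns averaged over the given sessions."""
    means = dataset.condition_means(modality)      # sessions x 4 x voxels
    return means[list(sessions)].mean(axis=0)


def _side_residuals(dataset, sessions):
    """Within session-x-condition residuals of both modalities, stacked."""
    res = []
    for mod in (0, 1):
        for ses in sessions:
            blocks = dataset.betas[mod, ses]
            labels = dataset.labels[mod, ses]
            for f in np.unique(labels):
                sel = labels == f
                res.append(blocks[sel] - blocks[sel].mean(axis=0))
    return np.concatenate(res, axis=0)


def crossnobis_rdm(
    dataset: SubjectDataset,
    shrinkage="fixed",
    noise_cov=None,
    normalize_by_voxels: bool = True,
) -> RDM:
    """Cross-validated Mahalanobis RDM over the 8 task conditions.

    For fold k with paired-session side A (session k of each task) and
    complementary side B (the other three sessions of each task),

        d(i, j) = (a_i - a_j)' Sigma^-1 (b_i - b_j) / P

    averaged over the four folds, where the condition patterns a, b are
    session means of the same-finger blocks and P is the voxel count (the
    division makes ROIs of different sizes comparable; disable with
    ``normalize_by_voxels=False``).

    Sigma is estimated per fold from the within-condition residuals of each
    side (shrunk toward its diagonal, pooled as the two-side average), unless
    an explicit ``noise_cov`` — a :class:`NoiseCov`, a matrix, or the string
    ``"identity"`` — is supplied.
    """
    S = dataset.n_sessions
    P = dataset.n_voxels
    n_cond = len(CONDITIONS)
    D = np.zeros((n_cond, n_cond))
    fixed_inv = None
    if noise_cov is not None:
        if isinstance(noise_cov, str) and noise_cov == "identity":
            fixed_inv = np.eye(P)
        else:
            sig = noise_cov.sigma if isinstance(noise_cov, NoiseCov) else np.asarray(noise_cov)
            fixed_inv = linalg.inv(sig)

    for k in range(S):
        side_a = [k]
        side_b = [s for s in range(S) if s != k]
        A = np.vstack(
            [_condition_means_for_sessions(dataset, m, side_a) for m in (0, 1)]
        )
        Bm = np.vstack(
            [_condition_means_for_sessions(dataset, m, side_b) for m in (0, 1)]
        )
        if fixed_inv is None:
            cov_a = shrinkage_covariance(_side_residuals(dataset, side_a), shrinkage)
            cov_b = shrinkage_covariance(_side_residuals(dataset, side_b), shrinkage)
            sigma = 0.5 * (cov_a.sigma + cov_b.sigma)
            inv = linalg.inv(sigma)
        else:
            inv = fixed_inv
        D += crossnobis_distances(A, Bm, inv)
    D /= S
    if normalize_by_voxels:
        D /= P
    return RDM(D=D, subject=dataset.subject_id)


def naive_mahalanobis_rdm(
    dataset: SubjectDataset,
    shrinkage="fixed",
    normalize_by_voxels: bool = True,
) -> RDM:
    """Non-cross-validated Mahalanobis RDM (positively biased under the null).

    Condition patterns are the overall session means; the same pattern
    difference multiplies itself through the inverse covariance, so noise
    contributes quadratically and the expected distance exceeds zero even
    for identical conditions.  Kept as the contrast that motivates the
    cross-validated estimator.
    """
    S = dataset.n_sessions
    all_sessions = list(range(S))
    M = np.vstack(
        [_condition_means_for_sessions(dataset, m, all_sessions) for m in (0, 1)]
    )
    cov = shrinkage_covariance(_side_residuals(dataset, all_sessions), shrinkage)
    inv = linalg.inv(cov.sigma)
    diff = M[:, None, :] - M[None, :, :]
    D = np.einsum("ijv,vw,ijw->ij", diff, inv, diff)
    if normalize_by_voxels:
        D /= dataset.n_voxels
    np.fill_diagonal(D, 0.0)
    return RDM(D=0.5 * (D + D.T), subject=dataset.subject_id)


def diag_offdiag_contrast(rdms) -> dict:
    """Same-finger vs different-finger distance in the execution-imagery block.

    Per subject, the mean of the 4 diagonal cells of the cross block (the
    executed finger vs the same imagined finger) is compared with the mean of
    the 12 off-diagonal cells (different fingers across tasks) by a
    two-tailed paired t-test.  A negative difference means that imagining a
    finger lands representationally closer to executing that same finger than
    to executing any other — the signature of a shared code.
    """
    rdms = list(rdms)
    if len(rdms) < 2:
        raise ValueError("need at least two subjects")
    diag_means, off_means = [], []
    eye = np.eye(4, dtype=bool)
    for r in rdms:
        block = r.cross_block()
        diag_means.append(block[eye].mean())
        off_means.append(block[~eye].mean())
    diag_means = np.asarray(diag_means)
    off_means = np.asarray(off_means)
    diff = diag_means - off_means
    if np.allclose(diff.std(ddof=1), 0.0):
        t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(diag_means, off_means)
    sd = diff.std(ddof=1)
    return {
        "diag_mean": float(diag_means.mean()),
        "diag_sd": float(diag_means.std(ddof=1)),
        "offdiag_mean": float(off_means.mean()),
        "offdiag_sd": float(off_means.std(ddof=1)),
        "t": float(t),
        "dof": len(rdms) - 1,
        "p": float(p),
        "d": float(diff.mean() / sd) if sd > 0 else 0.0,
        "per_subject_diff": diff,
    }


def _pair_cell(task: str, pair) -> tuple:
    base = 0 if task == "execution" else 4
    i = FINGERS.index(pair[0])
    j = FINGERS.index(pair[1])
    return base + i, base + j


def within_task_pair_table(rdms, posthoc: bool = False) -> dict:
    """2 x 6 finger-pair distance table with a two-way within-subject ANOVA.

    Builds the long-format table of the six within-task finger-pair distances
    for both tasks, runs a repeated-measures ANOVA (task x finger pair, with
    partial eta squared), and optionally Tukey HSD over the six pairs within
    each task.
    """
    import pingouin as pg

    rdms = list(rdms)
    if len(rdms) < 2:
        raise ValueError("need at least two subjects")
    rows = []
    for si, r in enumerate(rdms):
        for task in ("execution", "imagery"):
            for pair in FINGER_PAIRS:
                i, j = _pair_cell(task, pair)
                rows.append(
                    {
                        "subject": r.subject if r.subject != "subject" else f"s{si}",
                        "task": task,
                        "pair": f"{pair[0]}-{pair[1]}",
                        "distance": r.D[i, j],
                    }
                )
    table = pd.DataFrame(rows)
    degenerate = table["distance"].var() == 0
    if degenerate:
        # no variance anywhere: every effect is exactly null
        anova = pd.DataFrame(
            {
                "Source": ["task", "pair", "task * pair"],
                "F": [0.0, 0.0, 0.0],
                "p_unc": [1.0, 1.0, 1.0],
                "np2": [0.0, 0.0, 0.0],
            }
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = pg.rm_anova(
                data=table, dv="distance", within=["task", "pair"],
                subject="subject", effsize="np2", detailed=True,
            )
    out = {"table": table, "anova": anova}
    if posthoc:
        tk = {}
        for task in ("execution", "imagery"):
            sub = table[table.task == task]
            groups = [
                sub[sub.pair == f"{a}-{b}"]["distance"].to_numpy()
                for a, b in FINGER_PAIRS
            ]
            tk[task] = stats.tukey_hsd(*groups)
        out["tukey"] = tk
    return out


def classical_mds(rdm, dims: int = 3) -> dict:
    """Classical (Torgerson) MDS embedding of a dissimilarity matrix.

    The matrix entries are treated as squared distances: the Gram matrix
    ``G = -1/2 J D J`` (J the centering projector) is eigendecomposed and the
    top ``dims`` axes with positive eigenvalues are returned, scaled by the
    square root of their eigenvalues.  Negative eigenvalues — expected when
    crossnobis values are not exactly Euclidean — are reported and their axes
    dropped (with a warning when that leaves fewer than ``dims`` axes).
    """
    D = rdm.D if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    n_pos = int(np.sum(w > 1e-12))
    k = min(dims, n_pos)
    if k < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k} axes", RuntimeWarning
        )
    coords = V[:, :k] * np.sqrt(w[:k])
    return {"coords": coords, "eigenvalues": w, "n_positive": n_pos}
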