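"""ROI signal-change statistics, multiple-comparison correction, and the
study driver that ties generation, decoding and RSA into one reproducible
report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import decode, rsa
from .grids import Mask
from .synth import SynthConfig, generate_subject

__all__ = [
    "percent_signal_change",
    "holm_adjust",
    "StudyConfig",
    "run_study",
    "PRESETS",
]


def percent_signal_change(
    task_betas: np.ndarray,
    baseline_beta: np.ndarray,
    roi: Mask | None = None,
) -> float:
    """Mean ROI signal change of task blocks, as percent of baseline.

    psc = 100 * mean over ROI voxels and task blocks of (task beta / baseline
    beta), the baseline being the intercept beta of the same GLM (collapsing
    over fingers).  Inputs may be volumes on the mask's grid or already
    masked (blocks, voxels) / (voxels,) arrays.
    """
    task = np.asarray(task_betas, dtype=float)
    base = np.asarray(baseline_beta, dtype=float)
    if roi is not None and task.shape[-3:] == roi.grid.shape:
        from .roi import extract_patterns

        task = extract_patterns(task, roi)
        base = extract_patterns(base, roi)[0]
    task = np.atleast_2d(task)
    base = np.ravel(base)
    if np.any(base <= 0):
        raise ValueError("baseline beta must be positive everywhere in the ROI")
    return float(100.0 * np.mean(task / base))


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


PRESETS = {
    # the original cohort and its replication: same design, different size
    "original": {"n_subjects": 10, "seed": 11},
    "replication": {"n_subjects": 14, "seed": 23},
}


@dataclass
class StudyConfig:
    """Everything needed to regenerate one full synthetic study."""

    n_subjects: int = 10
    seed: int = 11
    synth: SynthConfig = field(default_factory=SynthConfig)
    schemes: tuple = decode.SCHEMES
    n_perm: int = 0               # 0 disables permutation tests
    shrinkage: str | float = "fixed"
    make_figures: bool = True
    roi_name: str = "hand-M1"

    @classmethod
    def preset(cls, name: str, **overrides) -> "StudyConfig":
        base = dict(PRESETS[name])
        base.update(overrides)
        return cls(**base)

    def subject_configs(self):
        # distinct seeds -> independent subjects, all reproducible from one seed
        root = np.random.SeedSequence(self.seed)
        for i, child in enumerate(root.spawn(self.n_subjects)):
            yield replace(self.synth, seed=int(child.generate_state(1)[0] % 2**31))


def _figures(out_dir, results, group, mean_rdm, mds):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    order = [s for s in decode.SCHEMES if s in set(results["scheme"])]
    means = [results[results.scheme == s]["accuracy"].mean() for s in order]
    sds = [results[results.scheme == s]["accuracy"].std(ddof=1) for s in order]
    ax.bar(order, means, yerr=sds, color="steelblue")
    ax.axhline(25, ls="--", c="gray", lw=0.8)
    ax.axhline(50, ls=":", c="gray", lw=0.8)
    ax.set_ylabel("accuracy (%)")
    ax.set_title("decoding accuracy by scheme (group mean ± SD)")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(out_dir / "accuracy.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mean_rdm.D, cmap="viridis")
    ax.set_xticks(range(8), mean_rdm.conditions)
    ax.set_yticks(range(8), mean_rdm.conditions)
    fig.colorbar(im, ax=ax, label="crossnobis distance")
    ax.set_title("group-mean RDM")
    fig.tight_layout()
    fig.savefig(out_dir / "rdm.png", dpi=110)
    plt.close(fig)

    coords = mds["coords"]
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = ["tab:red"] * 4 + ["tab:blue"] * 4
    ax.scatter(coords[:, 0], coords[:, 1] if coords.shape[1] > 1 else 0 * coords[:, 0],
               c=colors)
    for i, name in enumerate(mean_rdm.conditions):
        ax.annotate(name, coords[i, :2] if coords.shape[1] > 1 else (coords[i, 0], 0))
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.set_title("classical MDS of the group RDM")
    fig.tight_layout()
    fig.savefig(out_dir / "mds.png", dpi=110)
    plt.close(fig)


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Run the full pipeline on a cohort of synthetic subjects.

    Generates ``n_subjects`` independent subjects, runs every classification
    scheme (with optional permutation nulls), builds per-subject crossnobis
    RDMs, performs the group statistics (one-sample t-tests vs chance with
    Holm correction across schemes, the same-vs-different-finger contrast,
    the task x finger-pair ANOVA, classical MDS of the mean RDM) and, when
    ``out_dir`` is given, writes results.tsv, group_stats.tsv, per-subject
    and group RDM CSVs, mds_coords.tsv, summary.json and figures.

    Identical config and seed give byte-identical tables.
    """
    rows = []
    rdms = []
    for cfg in config.subject_configs():
        ds = generate_subject(cfg)
        for scheme in config.schemes:
            rec = decode.run_scheme(ds, scheme, roi_name=config.roi_name)
            if config.n_perm:
                perm = decode.permutation_null(
                    ds, scheme, n_perm=config.n_perm, seed=cfg.seed + 7
                )
                rec.p_perm = perm["p"]
            for direction, acc in rec.per_fold:
                rows.append(
                    {
                        "subject": ds.subject_id,
                        "roi": config.roi_name,
                        "scheme": scheme,
                        "direction": direction or "fold",
                        "accuracy": acc,
                        "chance": rec.chance,
                        "p_perm": rec.p_perm,
                    }
                )
            rows.append(
                {
                    "subject": ds.subject_id,
                    "roi": config.roi_name,
                    "scheme": scheme,
                    "direction": "mean",
                    "accuracy": rec.accuracy,
                    "chance": rec.chance,
                    "p_perm": rec.p_perm,
                }
            )
        rdms.append(rsa.crossnobis_rdm(ds, shrinkage=config.shrinkage))
    results = pd.DataFrame(rows)

    mean_rows = results[results.direction == "mean"]
    group_rows = []
    for scheme in config.schemes:
        sub = mean_rows[mean_rows.scheme == scheme]
        stats_ = decode.group_vs_chance(
            sub["accuracy"].to_numpy(), sub["chance"].iloc[0]
        )
        group_rows.append(
            {
                "roi": config.roi_name,
                "scheme": scheme,
                "mean": stats_["mean"],
                "sd": sub["accuracy"].std(ddof=1),
                "chance": sub["chance"].iloc[0],
                "t": stats_["t"],
                "dof": stats_["dof"],
                "p": stats_["p"],
                "d": stats_["d"],
            }
        )
    group = pd.DataFrame(group_rows)
    group["p_holm"] = holm_adjust(group["p"].to_numpy())
    group["significant"] = group["p_holm"] < 0.05

    contrast = rsa.diag_offdiag_contrast(rdms)
    pair_result = rsa.within_task_pair_table(rdms)
    mean_rdm = rsa.RDM(
        D=np.mean([r.D for r in rdms], axis=0), subject="group-mean"
    )
    mds = rsa.classical_mds(mean_rdm, dims=3)

    summary = {
        "n_subjects": config.n_subjects,
        "seed": config.seed,
        "group_stats": group.drop(columns=["significant"]).to_dict("records"),
        "significant_after_holm": group.loc[group.significant, "scheme"].tolist(),
        "rsa_contrast": {
            k: (float(v) if np.isscalar(v) else None)
            for k, v in contrast.items()
            if k != "per_subject_diff"
        },
        "mds_eigenvalues": [float(w) for w in mds["eigenvalues"]],
    }

    out = {
        "results": results,
        "group": group,
        "rdms": rdms,
        "mean_rdm": mean_rdm,
        "contrast": contrast,
        "pair_table": pair_result,
        "mds": mds,
        "summary": summary,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        group.to_csv(out_dir / "group_stats.tsv", sep="\t", index=False)
        for r in rdms:
            r.frame().to_csv(out_dir / f"rdm_{r.subject}.csv")
        mean_rdm.frame().to_csv(out_dir / "rdm_group.csv")
        coords = mds["coords"]
        pd.DataFrame(
            coords,
            index=mean_rdm.conditions,
            columns=[f"axis_{i+1}" for i in range(coords.shape[1])],
        ).to_csv(out_dir / "mds_coords.tsv", sep="\t")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        if config.make_figures:
            _figures(out_dir, mean_rows, group, mean_rdm, mds)
    return out
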