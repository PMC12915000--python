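"""Multi-voxel pattern classification schemes.

Four schemes over block-level beta patterns, all built on a one-against-one
linear SVM (fixed C = 1, raw betas — no normalization, which matters because
SVMs are scale-sensitive; the convention here is deliberate and asserted):

- ``within-exec`` / ``within-imag``: fourfold leave-one-session-out finger
  classification inside one modality (chance 25%).
- ``cross``: train on every session of one modality, test on every session of
  the other, both directions, finger labels (chance 25%).  This is the probe
  for a shared finger code between execution and imagery.
- ``between-modality``: collapse fingers and classify execution vs imagery
  blocks, leave-one-session-out with the held-out session of one modality as
  the test set, both directions (chance 50%).

Pairwise classifiers each cast one hard vote; the class with most votes wins
and exact ties go to the lowest class index.  Permutation nulls keep the
trained classifier fixed and shuffle the test labels, exactly mirroring how
the observed accuracy is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "FoldScheme",
    "AccuracyRecord",
    "OvOModel",
    "make_scheme",
    "train_ovo",
    "predict_vote",
    "run_scheme",
    "permutation_null",
    "group_vs_chance",
    "SCHEMES",
]

SCHEMES = ("within-exec", "within-imag", "cross", "between-modality")

EXEC, IMAG = 0, 1


@dataclass(frozen=True)
class Fold:
    """One train/test split over (modality, session) cells.

    ``label_kind`` selects what the classifier predicts: the finger of each
    block, or the modality it came from.
    """

    train: tuple            # ((modality, session), ...)
    test: tuple
    direction: str = ""
    label_kind: str = "finger"

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test cells overlap")


@dataclass(frozen=True)
class FoldScheme:
    scheme: str
    folds: tuple
    chance: float

    def __iter__(self):
        return iter(self.folds)


def make_scheme(scheme: str, n_sessions: int = 4) -> FoldScheme:
    """Build the fold structure of one classification scheme."""
    sessions = range(n_sessions)
    folds = []
    if scheme in ("within-exec", "within-imag"):
        mod = EXEC if scheme == "within-exec" else IMAG
        for held in sessions:
            folds.append(
                Fold(
                    train=tuple((mod, s) for s in sessions if s != held),
                    test=((mod, held),),
                )
            )
        chance = 25.0
    elif scheme == "cross":
        all_exec = tuple((EXEC, s) for s in sessions)
        all_imag = tuple((IMAG, s) for s in sessions)
        folds = [
            Fold(train=all_exec, test=all_imag, direction="exec->imag"),
            Fold(train=all_imag, test=all_exec, direction="imag->exec"),
        ]
        chance = 25.0
    elif scheme == "between-modality":
        for held in sessions:
            train = tuple(
                (m, s) for m in (EXEC, IMAG) for s in sessions if s != held
            )
            for mod, direction in ((EXEC, "test-exec"), (IMAG, "test-imag")):
                folds.append(
                    Fold(
                        train=train,
                        test=((mod, held),),
                        direction=direction,
                        label_kind="modality",
                    )
                )
        chance = 50.0
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return FoldScheme(scheme=scheme, folds=tuple(folds), chance=chance)


@dataclass
class AccuracyRecord:
    """Per-subject, per-ROI accuracy of one scheme."""

    subject: str
    roi: str
    scheme: str
    accuracy: float          # percent, averaged over folds (and directions)
    chance: float
    n_test_blocks: int
    per_fold: list = field(default_factory=list)      # (direction, accuracy %)
    p_perm: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must lie in [0, 100]")

    def direction_accuracy(self, direction: str) -> float:
        accs = [a for d, a in self.per_fold if d == direction]
        if not accs:
            raise KeyError(direction)
        return float(np.mean(accs))


@dataclass
class OvOModel:
    """k(k-1)/2 pairwise linear SVMs with hard-vote aggregation."""

    classes: np.ndarray
    pairs: list
    classifiers: list
    n_features: int


def train_ovo(patterns: np.ndarray, labels: np.ndarray, C: float = 1.0) -> OvOModel:
    """Train one linear SVM per unordered class pair on raw beta patterns."""
    patterns = np.asarray(patterns, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    pairs, clfs = [], []
    for a, b in combinations(classes, 2):
        sel = (labels == a) | (labels == b)
        clf = SVC(kernel="linear", C=C)
        clf.fit(patterns[sel], labels[sel])
        pairs.append((a, b))
        clfs.append(clf)
    return OvOModel(
        classes=classes, pairs=pairs, classifiers=clfs, n_features=patterns.shape[1]
    )


def predict_vote(model: OvOModel, patterns: np.ndarray) -> np.ndarray:
    """Hard-vote prediction; ties resolve to the lowest class index."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[1] != model.n_features:
        raise ValueError("pattern dimensionality does not match the model")
    votes = np.zeros((patterns.shape[0], model.classes.size), dtype=int)
    class_pos = {c: i for i, c in enumerate(model.classes)}
    for (a, b), clf in zip(model.pairs, model.classifiers):
        pred = clf.predict(patterns)
        for c in (a, b):
            votes[:, class_pos[c]] += pred == c
    # argmax returns the first (lowest-index) maximum, i.e. the lowest class
    return model.classes[np.argmax(votes, axis=1)]


def _fold_arrays(dataset, fold: Fold, patterns: np.ndarray | None):
    """Stack the block patterns and labels of a fold's train/test cells."""
    source = dataset.betas if patterns is None else patterns

    def stack(cells):
        X = np.concatenate([source[m, s] for m, s in cells], axis=0)
        if fold.label_kind == "finger":
            y = np.concatenate([dataset.labels[m, s] for m, s in cells])
        else:
            y = np.concatenate(
                [np.full(source[m, s].shape[0], m) for m, s in cells]
            )
        return X, y

    return stack(fold.train), stack(fold.test)


def run_scheme(
    dataset,
    scheme: FoldScheme | str,
    patterns: np.ndarray | None = None,
    roi_name: str = "roi",
    C: float = 1.0,
) -> AccuracyRecord:
    """Run one classification scheme on a subject.

    Parameters
    ----------
    dataset : SubjectDataset
        Provides block labels and, by default, the beta patterns.
    scheme : FoldScheme or scheme name
    patterns : array like ``dataset.betas`` but with any voxel count, optional
        ROI- or sphere-restricted patterns aligned with the dataset's
        (modality, session, block) indexing.

    Returns
    -------
    AccuracyRecord with the fold-averaged accuracy in percent.
    """
    if isinstance(scheme, str):
        scheme = make_scheme(scheme, dataset.n_sessions)
    fold_accs, n_test_total = [], 0
    for fold in scheme:
        (Xtr, ytr), (Xte, yte) = _fold_arrays(dataset, fold, patterns)
        model = train_ovo(Xtr, ytr, C=C)
        pred = predict_vote(model, Xte)
        fold_accs.append((fold.direction, 100.0 * np.mean(pred == yte)))
        n_test_total += len(yte)
    return AccuracyRecord(
        subject=getattr(dataset, "subject_id", "subject"),
        roi=roi_name,
        scheme=scheme.scheme,
        accuracy=float(np.mean([a for _, a in fold_accs])),
        chance=scheme.chance,
        n_test_blocks=n_test_total,
        per_fold=fold_accs,
    )


def permutation_null(
    dataset,
    scheme: FoldScheme | str,
    n_perm: int = 1000,
    seed: int | None = None,
    patterns: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Permutation test of a scheme's accuracy against label shuffling.

    The classifier is trained once per fold on the correct labels; each
    permutation then shuffles the held-out test labels and re-scores the
    fixed predictions, giving the null distribution of the fold-averaged
    accuracy.  ``p`` is the fraction of null accuracies at or above the
    observed one; ``significant`` flags observed accuracy beyond the 95th
    percentile of its null.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", RuntimeWarning)
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(scheme, str):
        scheme = make_scheme(scheme, dataset.n_sessions)

    fold_preds, fold_labels = [], []
    for fold in scheme:
        (Xtr, ytr), (Xte, yte) = _fold_arrays(dataset, fold, patterns)
        model = train_ovo(Xtr, ytr)
        fold_preds.append(predict_vote(model, Xte))
        fold_labels.append(yte)
    observed = 100.0 * float(
        np.mean([np.mean(p == y) for p, y in zip(fold_preds, fold_labels)])
    )
    null = np.empty(n_perm)
    for i in range(n_perm):
        accs = [
            np.mean(p == rng.permutation(y))
            for p, y in zip(fold_preds, fold_labels)
        ]
        null[i] = 100.0 * np.mean(accs)
    p = float(np.mean(null >= observed))
    return {
        "observed": observed,
        "null": null,
        "p": p,
        "significant": observed > np.percentile(null, 95),
    }


def group_vs_chance(accuracies, chance: float) -> dict:
    """Two-tailed one-sample t-test of subject accuracies against chance.

    Returns t, degrees of freedom (n - 1), two-tailed p and Cohen's d.
    Raises on fewer than two subjects or zero between-subject variance.
    """
    accs = np.asarray(
        [a.accuracy if isinstance(a, AccuracyRecord) else a for a in accuracies],
        dtype=float,
    )
    if accs.size < 2:
        raise ValueError("at least two subjects are required")
    sd = accs.std(ddof=1)
    if sd == 0:
        if np.allclose(accs, chance):
            return {"t": 0.0, "dof": accs.size - 1, "p": 1.0, "d": 0.0,
                    "mean": float(accs.mean())}
        raise ValueError("zero variance across subjects away from chance")
    t, p = stats.ttest_1samp(accs, popmean=chance)
    return {
        "t": float(t),
        "dof": accs.size - 1,
        "p": float(p),
        "d": float((accs.mean() - chance) / sd),
        "mean": float(accs.mean()),
    }
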