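# Methods

## The question the pipeline operationalizes

Executing a finger movement evokes a reliable, finger-specific multi-voxel
pattern in contralateral hand primary motor cortex (M1). The scientific
question is whether *imagining* the same movement re-uses that finger code.
The pipeline answers it with three instruments, all operating on block-level
GLM beta patterns:

1. **Cross-modal decoding** — train a 4-finger classifier on execution
   blocks, test on imagery blocks (and vice versa). Above-chance transfer
   implies a shared code.
2. **Crossnobis RSA** — measure representational distances among the 8
   conditions {execution, imagery} x {index, middle, ring, little} and test
   whether imagining finger *f* lands closer to executing *f* than to
   executing any other finger.
3. **Searchlight mapping** — localize where in a volume the finger code is
   decodable.

## Synthetic subjects

No raw data ships with the package; a generative model reproduces the
statistical structure every downstream stage assumes, so the whole pipeline
is testable end to end.

Each subject owns four latent finger patterns `v_f` (standard normal over
`P` voxels). Somatotopic overlap of neighbouring fingers is induced by
convolving the four patterns along the finger axis with the kernel
`[rho/2, 1, rho/2]` and rescaling to unit voxel variance; with the default
`rho = 0.4` this leaves neighbouring-finger correlations near 0.4 and
next-neighbour correlations an order smaller, which is what makes
adjacent-finger pairs harder to discriminate and representationally closer
— an emergent, not hand-coded, adjacency effect.

A block-level beta pattern is

    execution:  a_E * v_f         + m * u_E + eps,   eps ~ N(0, Sigma_E)
    imagery:    s  * a_E * v_f    + m * u_I + eps',  eps' ~ N(0, Sigma_I)

- `s` (imagery scale, default **0.3**) is the core modelling commitment:
  imagery re-uses the *same* pattern directions at reduced amplitude — a
  scaled-down shared finger code. `s = 0` removes all cross-modal finger
  information and is the null condition for calibration tests.
- `m * u` (modality offset, default **m = 15** with `u` a fixed random unit
  vector per modality and subject) is finger-independent. It gives the
  between-modality classifier something real to decode and makes the first
  MDS axis separate execution from imagery, without contributing anything
  to finger decoding in either modality.
- Noise is spatially correlated with an AR(1) profile over the voxel
  ordering (`cov = sd^2 * phi^|i-j|`, default `phi = 0.3`); the true
  covariance is retained on the dataset so whitening can be validated.
- Imagery noise exceeds execution noise (`sigma_I > sigma_E` by default):
  imagined movements produce weaker, more variable patterns. This is also
  what reproduces the empirically observed asymmetry that a decoder trained
  on imagery and tested on execution outperforms the reverse direction —
  the imagery-trained boundary is noisier, but it is evaluated on
  high-amplitude, low-noise execution patterns, whereas the reverse
  direction evaluates a clean boundary on weak, noisy imagery patterns.

Defaults (`P = 370` voxels, matching the mean hand-M1 ROI size the design
emulates; 2 modalities x 4 sessions x 12 blocks, 3 blocks per finger per
session; `a_E = 1`, `sigma_E = 4`, `sigma_I = 6`) were fixed once, by a coarse sweep, to
reproduce the *qualitative ordering* of the group results the design
emulates — within-execution decoding far above chance,
cross-modal decoding modestly but reliably above 25%, within-imagery near
chance, between-modality decoding high, execution within-task distances
larger than imagery ones, and same-finger execution-imagery distances
shorter than different-finger ones. No attempt is made to match printed
accuracy values quantitatively; only the structure of the findings is a
calibration target.

What the generator does **not** model: head motion, physiological noise
spectra, spatial autocorrelation beyond the AR(1) line ordering, anatomical
geometry (masks are synthetic rectangles/spheres), session-level scanner
drifts in the beta domain, or subject-level variation in ROI size. Passing
tests therefore demonstrate correctness of the *analysis machinery* under
the model's assumptions, not performance on real fMRI data.

## GLM

Each 12-s task block gets its own boxcar regressor (12 per session),
convolved at 0.1-s microtime resolution with a canonical double-gamma HRF
(response mode 6 s, undershoot mode 16 s, unit dispersions, undershoot
ratio 1/6, 32-s support, peak-normalized) and sampled at the TR = 3 s
acquisition times of the 98 retained scans. Low-frequency drift is modelled
with a discrete-cosine basis containing every component whose period
exceeds the 128-s cutoff (4 columns at 98 scans), plus an intercept —
modelling the drift rather than filtering the data keeps degrees of freedom
explicit. Estimation is OLS; an optional two-pass AR(1) prewhitening
(single pooled lag-1 coefficient) is available but off by default, because
the block-level betas feed cross-validated analyses whose results are
fold-level, not whitening-level.

## ROI definition

Functional ROIs threshold a localizer t-map at an uncorrected one-tailed
p < 0.01 (activation; the positive tail is an explicit convention),
optionally drop 6-connected components below an extent `k`, and intersect
with an anatomical mask. Patterns are extracted in fixed lexicographic
voxel order and are **never scaled or centred** — the decoders consume raw
betas, a deliberate convention worth stating loudly because SVMs are
scale-sensitive.

## Decoding

One-against-one linear SVMs (C = 1 fixed, no hyperparameter search):
k(k-1)/2 binary classifiers, each casting one hard vote; most votes wins
and exact ties resolve to the lowest class index (the common OvO library
convention; any other fixed rule would do, but it must be fixed). The
binary unit is libsvm's linear SVC; the voting, schemes and inference are
implemented here.

Schemes: within-modality finger decoding is fourfold leave-one-session-out
(train 3 sessions / test 1, 12 test blocks per fold, chance 25%);
cross-modal decoding trains on all four sessions of one modality and tests
on all four of the other, both directions averaged (chance 25%);
between-modality decoding collapses fingers and classifies execution vs
imagery blocks, leave-one-session-out with the held-out session of one
modality as test set, both directions (chance 50%). Train/test disjointness
is asserted on every fold.

The permutation null trains once per fold on correct labels and shuffles
only the held-out test labels per permutation (1000 by default), rescoring
the fixed predictions. This mirrors exactly how the observed accuracy is
assembled; it is cheaper than the retrain-per-permutation null and is the
documented convention here. `p` is the fraction of null accuracies at or
above the observed value.

Group inference is a two-tailed one-sample t-test of subject accuracies
against chance, Holm-corrected across schemes/ROIs, with Cohen's d.

## Searchlight

A 9-mm sphere on the 3-mm grid holds 123 voxels when uncut (the analytic
lattice count); spheres are clipped at the mask edge and centres whose
clipped sphere falls below `min_voxels` (default 100) are skipped. The
fold-averaged scheme accuracy is written to the centre voxel. Group maps
are thresholded voxelwise (one-sample t vs chance, one-tailed, p < 0.0005
uncorrected) with a cluster-extent rule (k >= 10, 6-connectivity), and
clusters are reported with size, peak t and peak coordinates. Permutation
testing is deliberately not offered at searchlight level; its cost is out
of proportion to its value next to the ROI tests.

## Crossnobis RSA

Distances are cross-validated Mahalanobis: with condition pattern estimates
`a` and `b` from two independent partitions and noise covariance `Sigma`,

    d(i, j) = (a_i - a_j)' Sigma^-1 (b_i - b_j) / P.

Because the two difference estimates are independent, `E[d] = 0` when the
conditions do not differ — the estimator is unbiased and individual cells
may be negative (a negative value means the two partitions disagree about
the direction of the pattern difference). The package also computes the
non-cross-validated Mahalanobis distance, which is positively biased under
the null; the bias gap is asserted in tests, since it is the entire reason
for cross-validating.

Partitioning: fold k pairs session k of execution with session k of
imagery (8 condition patterns, each the mean of its 3 same-finger blocks);
the complementary six sessions form the other partition. Four folds are
averaged. Design choices that the literature leaves open, fixed here:

- Condition patterns are session means of block betas (run-wise estimates),
  not individual blocks.
- Distances are divided by the voxel count `P`, making ROIs of different
  sizes comparable; toggleable (`normalize_by_voxels=False`).
- `Sigma` is estimated per partition from within-condition block residuals,
  shrunk toward its diagonal, and the two partitions' estimates are
  averaged before inversion.
- Shrinkage intensity defaults to the fixed value **0.4** (a value that
  behaves well on fMRI patterns whose sample covariance is rank-deficient);
  an analytic optimal-shrinkage estimator (ratio of summed sampling
  variances of off-diagonal covariances to their summed squares, clipped to
  [0, 1]) is available as `mode="optimal"`. Positive definiteness is
  guaranteed, with a logged diagonal jitter in degenerate cases.

Group analyses: (a) the same-finger vs different-finger contrast in the
4x4 execution-imagery block (two-tailed paired t-test; negative difference
= shared code); (b) the 2 x 6 within-task finger-pair table with a two-way
repeated-measures ANOVA (task x pair, partial eta squared; Tukey HSD on
request); (c) classical (Torgerson) MDS of the mean RDM — entries treated
as squared distances, double-centred, eigendecomposed; negative eigenvalues
(expected, since crossnobis values are not exactly Euclidean) are reported
and their axes dropped with a warning when that truncates the requested
dimensionality.

## Numerical and degenerate-input conventions

- All randomness flows from one integer seed through `numpy` SeedSequence
  spawning; identical config + seed gives byte-identical output tables.
- Rank-deficient designs require an explicit flag (pseudo-inverse with a
  warning); dimension mismatches and non-finite betas inside masks raise.
- Zero between-subject variance: t = 0 / p = 1 when all values equal the
  null, an error otherwise (a silent infinite t would be worse).
- The DCT drift count uses strictly "period > cutoff" (an exact multiple
  contributes one fewer column).
- Accuracy is always percent in [0, 100]; chance is 25 or 50 by scheme.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at sizes chosen to give the relevant law of
large numbers room without waste: 50 subjects for chance-level calibration
of the cross and between-modality schemes, 200 pure-noise subjects (120
voxels) for crossnobis unbiasedness, 100 groups of 14 subjects at default
conditions for the qualitative-structure recovery rates, 100 subjects for
permutation type-I calibration, and reduced voxel counts (40-120) wherever
the property under test does not depend on ROI size.

## Known limitations

- The generator's shared code is exact in direction (`v_f` identical across
  modalities unless `imagery_jitter > 0`); real imagery patterns likely
  rotate as well as shrink.
- OLS ignores serial correlation unless AR(1) is switched on; no attempt is
  made to match any particular packaged GLM implementation numerically.
- Searchlight maps are computed serially; whole-brain grids at realistic
  sizes are slow in pure Python (the intended use here is method validation
  on modest grids).
- The RM-ANOVA relies on pingouin's implementation (no sphericity
  correction is applied to the reported uncorrected p in the two-way case
  beyond what pingouin provides).
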