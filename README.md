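# fingermvpa

**Cross-modal multi-voxel pattern analysis of finger representations in
motor cortex.**

When you imagine tapping a finger, does hand primary motor cortex (M1)
re-use the neural finger code it deploys when you actually tap it?  This
package implements the complete analysis pipeline for that question —
block-design GLM beta estimation, localizer-based ROI masking, one-vs-one
linear SVM decoding within and across modalities, permutation nulls,
searchlight mapping, and crossnobis representational similarity analysis —
together with a synthetic-subject generator that emulates a shared,
scaled-down finger code between motor execution and motor imagery, so
every stage is testable end to end without any scanner data.

It is aimed at researchers who want a tested, reproducible reference
implementation of the cross-classification + crossnobis-RSA methodology,
or a simulation sandbox for its statistical behaviour (chance-level
calibration, permutation validity, crossnobis unbiasedness, power of the
group contrasts).

## The methods in brief

**Cross-classification.**  Block-level beta patterns (12 task blocks per
session, 4 sessions per modality, 3 blocks per finger) feed a one-against-one
linear SVM (fixed C = 1, raw betas, no normalization): k(k−1)/2 = 6 pairwise
classifiers vote, most votes wins.  Within-modality decoding is fourfold
leave-one-session-out (chance 25%); cross-modal decoding trains on all
execution sessions and tests on all imagery sessions and vice versa.
Above-chance cross-modal transfer is the decoding signature of a shared
finger code.

**Crossnobis RSA.**  The 8×8 representational dissimilarity matrix over
{execution, imagery} × {index, middle, ring, little} uses the
cross-validated Mahalanobis distance

d(i, j) = (â_i − â_j)ᵀ Σ̂⁻¹ (b̂_i − b̂_j) / P

with condition estimates â, b̂ from independent session partitions and a
shrinkage noise covariance Σ̂ (fixed λ = 0.4 toward the diagonal by
default).  Cross-validation makes E[d] = 0 when conditions do not differ,
so distances are unbiased and may be negative.  A shared code shows up as
the same-finger execution–imagery distances being shorter than the
different-finger ones, and as a common finger-pair geometry across tasks.

**Synthetic subjects.**  Each subject has four latent finger patterns
v_f with somatotopic neighbour correlation; execution blocks are
a·v_f + m·u_E + noise, imagery blocks are s·a·v_f + m·u_I + noise with
s < 1 — imagery re-uses the execution code at reduced amplitude.  See
`docs/methods.md` for every parameter, default and modelling assumption.

## Worked example

`examples/` contains one short script per capability.  Running
`python examples/03_roi_decoding.py` decodes one synthetic subject:

```
within-exec        accuracy  91.67%  (chance 25%)
within-imag        accuracy  25.00%  (chance 25%)
cross              accuracy  50.00%  (chance 25%)
between-modality   accuracy  85.42%  (chance 50%)
  exec->imag 45.83%, imag->exec 54.17% (training on the noisier imagery data
  and testing on clean execution patterns is typically the better direction)
permutation test: observed 50.00%, p = 0.000 over 1000 label shuffles
```

Finger identity is decoded well above 25% within execution, near chance
within imagery, and — the key result pattern — modestly but reliably above
chance *across* modalities, implying the imagery patterns carry a readable
copy of the execution finger code.  `examples/06_full_study.py` runs a
10-subject study end to end and writes the full report (accuracy tables,
Holm-corrected group tests, per-subject RDMs, MDS coordinates, figures);
`examples/05_crossnobis_rsa.py` prints the group RDM, the same- vs
different-finger contrast and the task × finger-pair ANOVA.

A thin CLI wraps the same library calls:

```bash
mvpa-study synth --preset original --out cohort/     # NIfTI betas + TSVs
mvpa-study decode --betas b0.nii --betas b1.nii --blocks blocks.tsv \
                  --mask roi.nii --scheme cross --out results.tsv
mvpa-study run config.yaml --out report/
```

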