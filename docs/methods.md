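# Methods

## Data model

A *measure* is one subjects × features block with an anatomical group tag
(`cortical`, `subcortical`, `wholebrain`, `gica`). The default inventory
has fourteen blocks mapped onto twelve *weighted measures*: the
whole-brain intensity and whole-brain global-connectivity blocks share the
fusion weights (and the per-measure accuracy estimates) of their
subcortical counterparts through the `weight_key` field. This keeps the
hybrid formula's subcortical sum at exactly four distinct weights while
preserving the 748-column total (449 cortical, 76 subcortical, 52
whole-brain, 171 group-ICA). Subject order is canonicalized to the label
file's order at assembly; missing or non-numeric cells are hard errors
naming the offending subject and feature, because upstream quality control
is out of scope here and silent imputation would mask misaligned tables.

## Connectivity features

Voxel time series are demeaned and scaled to unit Euclidean norm, after
which Pearson correlation is the plain dot product. The per-voxel
global-connectivity value is `u_i · ū` with `ū` the voxel-average of the
unit-norm rows — algebraically the row mean of the full correlation matrix
*including* the voxel's own r = 1 term, at O(M·T) cost instead of O(M²·T).
The exclusive mean is `(M·v − 1)/(M − 1)` if needed. The GCOR scalar is
`‖ū‖²`, the mean of all M² pairwise correlations, which makes
`gcor = mean(map)` an exact identity and bounds GCOR in [0, 1]; the
unsquared norm is available via `squared=False` because both readings of
the scalar circulate in the literature, but only the squared form is a
mean correlation. Fisher z uses `atanh` with |r| clipped at 1 − 1e-7 to
stay finite. ROI averaging operates on whichever scale the caller passes;
the pipeline applies it after the Fisher transform. Component
connectivity is the strict upper triangle (row-major) of the K × K
correlation matrix of component time-courses: K = 19 gives the 171-element
feature vector.

## ELM classifier

Input weights and biases are drawn uniform on [−1, 1] from a seeded
`numpy` generator (the classical ELM choice; nothing in the method depends
on the distribution's details), activation is the logistic sigmoid with
tanh behind a flag, targets are one-hot in {−1, +1}, and the output
weights are `pinv(H) · T` with an SVD pseudo-inverse at relative cutoff
1e-12 — the unregularized minimum-norm least-squares solution. Prediction
is argmax over output nodes with ties resolved toward the first class in
the model's encoding. The only hyperparameter is the hidden-node count;
`tune_hidden_nodes` scans a candidate list by seeded stratified inner CV
and returns the first maximizer. Candidates at or above the inner training
size are evaluated (the pseudo-inverse handles the underdetermined system)
but trigger an overfitting warning.

## Evaluation protocol

Nested n×k-fold CV (default 10 repeats of stratified 10-fold): per fold,
features are min–max scaled to [−1, 1] on the training partition only
(train min → −1, train max → +1, constant features → 0; test values may
leave the interval), hyperparameters are tuned on inner folds of the
training partition, and confusion counts are recorded on the held-out
fold. `scaling_mode="global"` reproduces pipelines that scale before
splitting; `tuning_mode="paper_replication"` selects the hidden-node count
by outer test-fold accuracy — both are deliberately available because they
are common in the literature, and both are optimistically biased.
Stratification is the default for the balanced two-class design;
unstratified folds are a flag. Metrics are the six confusion-matrix
ratios; a 0/0 ratio is NaN and excluded from fold averages rather than
coerced. Fold seeds derive arithmetically from the config seed
(`repeat_split_seed`, `fold_train_seed`), so an external loop can
reproduce any fold bit-for-bit.

The permutation test re-runs the identical CV procedure on label
permutations and reports the add-one estimate `p = (1 + b)/(1 + m)`, with
ties (`permuted ≥ observed`) counting against significance. The estimator
can never return 0; its floor at 10,000 permutations is 1/10,001 ≈ 0.0001.
Labels are permuted before the CV split and the full procedure (splits,
scaling, tuning) reruns per permutation — the strict variant.

## Fusion

Weights are `W_i = 1 − A_max + A_i` at full precision (display rounding to
4 decimals only). The scheme is shift-consistent (only `A_i − A_max`
matters) and the arg-max measure's weight is exactly 1 by construction.

Two ordering decisions matter:

1. **Scale before weighting, never rescale after.** Min–max scaling is a
   per-feature affine map, so rescaling a weighted matrix cancels the
   scalar block weights exactly. Blocks are scaled first and the fused
   matrix enters the classifier unrescaled (`scaling_mode="none"` in the
   CV when the matrix is pre-fused); `rescale_after_fusion=True` exists to
   demonstrate the cancellation. The same per-feature property means every
   variant factors into scale-then-column-multiply, which
   `column_weights` exposes and `nested_cv_fused` exploits.

2. **Where the weights come from.** Estimating per-measure accuracies on
   the whole cohort reuses test subjects in weight estimation. The default
   fused evaluation (`nested_cv_fused`, `weighting="within_fold"`)
   re-estimates accuracies and weights inside each outer training
   partition; `weighting="whole_dataset"` reproduces the single-pass
   protocol that tabulates one weight table for the whole cohort. The
   report's displayed weight ranking is always the whole-cohort table
   (that is what a weight table describes); the fused *accuracies* default
   to the leakage-free protocol.

In `run_experiment`, the optional permutation test permutes labels over
the fixed hybrid matrix built with whole-cohort weights (scaling already
applied), so each permutation costs one CV run rather than a full
weight-refit; the strict full-refit variant is available by calling
`permutation_test` around `nested_cv_fused` directly, at proportionally
higher cost.

## Synthetic data

Per measure, class-conditional Gaussians: the first
`ceil(informative_fraction · d)` columns have class means separated by the
effect size δ (in noise-SD units) and are equicorrelated at ρ via a shared
factor; remaining columns are iid noise. Per-feature separability is
analytic (two-sample AUC = Φ(δ/√2)). Defaults: informative fraction 0.5,
ρ = 0.2, noise scale 1. The default spec (`table2_spec`) fixes the
study-sized inventory — 72 + 72 subjects, fourteen blocks, 748 features —
with fixed unequal effect sizes between 0.5 and 1.0 (group ICA 1.0) so
per-measure accuracies differ and the weighting has work to do.

What the generator does *not* emulate: marginal distributions of real
morphometry (skew, site effects, outliers), cross-measure correlation
(each block is drawn independently given the label), demographic
covariates, and the real study's accuracy level — the defaults yield
per-measure accuracies around 0.5–0.65 at n = 144 rather than ~0.9.
Passing tests therefore demonstrate the method's algebra, determinism and
statistical calibration, not classification performance on real imaging
features.

## Problem sizes in the test suite

Tests exercise the protocol at reduced sizes chosen as the smallest that
still discriminate correct from incorrect behavior: oracle equivalences on
50-voxel volumes and 20–30-sample ELM fits; the permutation-null
calibration on 40 subjects × 20 null features with 200 permutations × 200
replicates and a 5-fold, 1-repeat CV around a fixed 10-node ELM; fusion
behavior on cohorts of 30–80 subjects with 3–5-fold CV. The full
10×10-fold protocol with the 90–220 node search is the library default
for real use.

## Known limitations

- Binary classification only in practice (the interface permits more
  classes; tests and defaults target two).
- The hidden-node "greedy search" is an exhaustive scan with
  first-maximum tie-breaking; no early stopping.
- Permutation p-values inherit the discreteness of fold accuracies; with
  few permutations and small cohorts the test is conservative (ties count
  against significance).
- ROI labelings are opaque identifiers; no atlas geometry or neuroimaging
  binary formats are read.
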