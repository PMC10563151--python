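# Methods

## Problem setting

A flow-cytometry sample is a set X_i = {x_i1, ..., x_in_i} of per-cell
measurement vectors (fluorescence markers and scatter parameters); n_i
varies by sample.  Supervision exists only at the sample level: a binary
diagnosis y_i^L and/or a cancer burden y_i in [0, 1], the fraction of the
sample's cells that are pathogenic.  Cell-level pathogenicity indicators
z_ij are never observed.  The package learns a per-cell scoring function
s(x; phi) = P(z = 1 | x) from this weak supervision, predicts sample-level
outcomes from the scores, and post-hoc explains which cells drove the
prediction.

## Model

The scoring network is a feedforward map with ReLU hidden layers and a
sigmoid output, so every cell score lies in (0, 1).  The sample statistic
is the plain mean s̄_i = (1/n_i) Σ_j s(x_ij; phi) — a permutation-invariant
pooling, so the model is a set function by construction.  Two objectives
link s̄ to the targets:

* **Burden regression.**  L(phi) = Σ_{i: y_i>0} (s̄_i − y_i)² +
  λ Σ_{i: y_i=0} s̄_i², with λ > 1.  The second term pushes healthy samples'
  burden estimates to zero; λ > 1 is enforced.  The prediction ŷ_i = s̄_i.
* **Binary classification.**  P(y^L=1 | X_i) = 1/(1 + exp(α + β s̄_i)) with
  learnable α, β, trained by cross-entropy over samples; the positive-class
  term can be weighted by w > 0.  As written, P is *decreasing* in s̄ when
  β > 0, so the sign of the learned β decides whether a high raw score means
  pathogenic.  The package therefore reports an *oriented* score — s when
  ∂P/∂s̄ > 0 (β < 0), otherwise 1 − s — so "high = pathogenic" always holds;
  the raw scores are retained alongside.  Class calls threshold P at 0.5.

Both losses are sums over samples (not means), so λ and w keep the same
meaning whatever the cohort size.

## Density-based initialization

Training from random weights must discover which cells distinguish positive
from negative samples.  A closed-form head start comes from Bayes' rule: for
a cell x in a positive sample with burden y,

    s'(x) = 1 − p_healthy(x) · (1 − y) / p_sample(x),

clipped to [0, 1], where p_healthy is estimated by KDE on the pooled cells
of all negative training samples (healthy cells are assumed identically
distributed in positive and negative samples) and p_sample by KDE on the
positive sample's own cells.  Cells of negative samples get s' = 0 by
definition.  With binary labels only, 1 − y is replaced by a fixed prior
P(z=0 | y>0), default 0.9.  A network pretrained to reproduce s' (MSE over
cells) supplies the initial weights phi' for end-to-end training.  The mean
of s' is itself a crude burden estimate — the density-only baseline used in
the ablation; for unlabeled samples its prior is solved self-consistently
(y = mean s'(y), damped fixed-point iteration).

KDE details.  The kernel is a product of per-channel Gaussians with
bandwidths from Scott's rule, h_d = σ_d m^(−1/(D+4)) (Silverman and fixed
bandwidths available); all evaluation is in log space.  Fitting subsamples
to `max_fit_cells` (default 50 000) with a fixed seed.  Two numerical
choices matter in 8–16 channels:

* **Leave-one-out self-evaluation.**  A KDE queried at its own fit points
  includes each point's own kernel mass; at desk-scale m in 8 channels this
  inflates p_sample by ~30% against p_healthy and biases s' upward.  The
  per-sample KDE is therefore evaluated leave-one-out at its own cells.
* **float32 pairwise kernels.**  Squared distances go through the Gram
  expansion on bandwidth-scaled coordinates (BLAS matmul) in float32 with a
  per-row max shift before exponentiation.  The ~1e-4 absolute error in log
  density this costs is far below every tolerance used; isolated points
  cannot underflow to −inf because of the shift.

Clipping handles the fact that the density ratio can exceed 1/(1−y); the
ratio form is evaluated entirely as log p_healthy + log(1−y) − log p_sample.

## Training protocol

Adam (lr default 5e-3) on full-cohort batches for a fixed number of epochs
(default 200).  Each epoch may subsample every sample to a per-sample cell
cap (default 1000) — the subsample mean is an unbiased estimate of s̄ and
keeps an epoch's cost independent of acquisition depth; prediction and all
reported statistics always use every cell.  Training runs `n_restarts`
times (default 5) from phi' (when density initialization is on) or from
fresh random weights, with the restart's seed offset by its index; the
restart with the lowest validation loss is kept, validation AUROC breaking
ties, training loss standing in when no validation cohort exists.  In
classification mode α, β are initialized mildly negative in β (N(−2, 0.5))
so the logistic starts oriented with "high score = disease", but training is
free to flip it; the orientation wrapper makes reported scores insensitive
to the outcome.  A restart that produces a non-finite loss is marked failed;
the run errors only if all restarts fail.  Hyperparameter search is a grid
over (λ or w, learning rate) scored by mean validation AUROC over
class-stratified folds, followed by a refit on the full training cohort.

The scoring network, its backpropagation and the Adam update are implemented
directly on NumPy arrays; the model is small enough (two hidden layers,
default 64/32) that this is fast, exactly reproducible, and free of
framework nondeterminism.

## Preprocessing

Fluorescence channels default to arcsinh(x / 150); scatter channels to
min–max scaling with extrema fit on the training cohort only; both are
per-channel configurable, monotone, and invertible (interpretation outputs
report cutoffs in original units through the inverse).  No compensation and
no debris/doublet prefiltering are applied: clinical exports are assumed
compensated, and the model is meant to see unfiltered events.

## Interpretation

* **Cell labels.**  Oriented score ≥ threshold (default 0.5; ties positive).
* **Global phenotype tree.**  CART (Gini, axis-aligned splits, default depth
  4, min leaf 1% of cells, impurity-decrease floor 1e-3) fit on the pooled
  labeled cells.  The impurity floor stops the tree from splitting a
  near-pure population to isolate a handful of stray cells, keeping one leaf
  per phenotype; cutoffs are reported in transformed and original units.
  Single-class labels yield a one-leaf tree with a warning.
* **Per-sample projection.**  Each sample's cells are routed down the fixed
  global tree; per-node counts conserve exactly (children sum to parent).  A
  leaf is a "positive path" for a sample when the sample's cells there are
  majority labeled-positive (≥ 0.5) *and* the leaf holds at least 5% of the
  sample's positive cells — the coverage floor keeps a few boundary cells
  from flagging a path.
* **Cancer-only clusters.**  K-means (default k = 8, fixed seed, per-sample
  subsample cap 5000 so deep acquisitions do not dominate) over pooled
  cells.  A cluster is cancer-only when its median prevalence across
  positive samples is ≥ p_hi (default 1%) and its maximum prevalence across
  negative samples is ≤ p_lo (default 0.2%).  This check never sees the
  model; its Jaccard overlap with the thresholded cell labels is the
  independent validation statistic.
* **Dot plots.**  Per marker pair, (x, y, label) tables in original units
  with the tree's cutoffs as reference lines.

## Synthetic cohorts

The generator draws each sample from a Gaussian mixture in transformed
marker space: shared healthy populations in every sample; pathogenic
populations only in positive samples, mixed in with the drawn nominal burden
as the pathogenic weight (realized fraction recorded as the sample's
burden, so targets are exact); per-sample mean jitter N(0, jitter_sd² I) on
every population models between-patient heterogeneity; cell counts are
uniform over a configured interval.  Positive samples carry either one
endotype each or a within-sample mixture.

The standard benchmark used by the tests and the reproduction script: 8
markers, 3 healthy populations (σ = 0.5, mixing 0.5/0.3/0.2), 2 pathogenic
endotypes each shifted 3 transformed units (6 population SDs) on its two
defining markers — the separation a marker-positive blast population shows
against marker-negative normal cells on the arcsinh scale, and the reason
such phenotypes are gateable — with both endotypes present in every
positive sample, jitter_sd 0.15, burdens Uniform(0.05, 0.9), 5000–10000
cells per sample, 40 training + 20 test samples (half positive).  Problem
sizes used elsewhere: KDE fit caps of 20 000 cells (8-marker benchmark) and
50 000 (1-D closed-form check), pretraining 150 epochs, training 200 epochs
× 5 restarts with a 25% validation split.

What the generator does *not* emulate — and what passing tests therefore do
not show — includes: spillover and compensation artifacts, debris/doublets,
instrument drift, non-Gaussian population shapes (skewed or curved clouds),
burden-correlated phenotype drift, and minimal-residual-disease regimes
(burdens below 5% are outside the default burden range; very small
populations are a known weak point of the global objective).

## Known limitations

* The mean-aggregation objective can overlook very small (<1%) populations
  and MRD-scale burdens; nothing in the loss targets them specifically.
* The density-only baseline is sensitive to between-sample heterogeneity:
  jitter alone moves a healthy sample's own density away from the pooled
  healthy density and inflates its mean s' (measured ≈ 0.23 at jitter_sd
  0.15); the end-to-end trained model does not inherit this bias.
* Binary-label initialization uses a single fixed prior for all positive
  samples, a deliberate simplification.
* The per-channel-bandwidth KDE ignores channel correlations; in strongly
  correlated panels a full-covariance or transformed-space estimate would be
  sharper.
* Scores near a sample's decision boundary are not calibrated
  probabilities; only the orientation and ranking are validated at the cell
  level.
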