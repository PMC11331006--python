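# Methods

This note documents the modelling choices, defaults and study conditions
behind `msfn`, and what the synthetic experiments do and do not establish.

## Problem and labels

The task is binary 5-year survival classification from three patient-level
views: clinical covariates (mixed discrete/continuous), gene expression
(continuous) and copy-number variation (discretized to {−2,…,2}). Labels
derive from follow-up: patients with ≥ 60 months of follow-up are long-term
survivors (1); patients who died before 60 months are short-term survivors
(0); patients censored before 60 months have no determinable 5-year outcome
and are **excluded**. Exclusion is the standard convention for binary
survival labels; it is a choice, not a theorem — alternatives (e.g.
inverse-probability-of-censoring weighting) are out of scope.

## Preprocessing

Features, then samples, with more than 20% missing values are dropped
(feature-first retains more patients). Continuous features are imputed by
the mean of the k = 5 nearest patients (missing-aware Euclidean distances;
scikit-learn's `KNNImputer` provides the mechanism) and min-max scaled to
[0, 1]; discrete features are imputed by the per-feature mode with ties
broken toward the smallest value. CNV values pass through untouched: they
are already discrete codes, and rescaling them would destroy their
interpretation. The pipeline (filter → impute → scale) is idempotent on its
own output.

## mRMR feature selection

Expression and CNV features are ranked by greedy minimum-redundancy
maximum-relevance with the MID (difference) criterion: the first feature
maximizes mutual information with the label; each next feature maximizes
`MI(f; y) − mean_{s∈selected} MI(f; s)`. Continuous features are discretized
into 3 equal-frequency bins first; MI is computed in nats from the
contingency table. Ties break toward the lexicographically smaller feature
name, making the ranking deterministic and invariant to patient order. The
MIQ (quotient) criterion is available as an option. **Selection is fitted on
training folds only** inside cross-validation; ranking the full cohort once
would leak test labels into the folds.

## Similarity network fusion

Per view, affinities are `W_ij = exp(−d²_ij / (λ ε_ij))` with
`ε_ij = (μ_i + μ_j + d_ij)/3`, where `μ_i` is patient i's mean distance to
its k nearest neighbours; this three-term average removes per-view scale.
Defaults: `λ = 0.5`, `k = max(n/10, 3)`, 20 diffusion iterations — standard
values in the network-fusion literature. The full kernel is normalized to a
transition matrix with diagonal 1/2 (half the probability mass stays on the
patient); the local kernel row-normalizes each patient's k strongest
neighbours.

Each cross-diffusion step computes
`P(v) ← L(v) · mean_{u≠v} P(u) · L(v)ᵀ`, re-symmetrizes, and **renormalizes
back to the half-mass transition form** (diagonal pinned to 1/2). The
renormalization form matters: if the updated matrices are only rescaled to
row-stochastic, the iteration is a Markov-chain mixing process and
converges to an essentially uniform matrix — all similarity structure is
destroyed (we measured same-class and different-class mean edge weights
agreeing to 2 × 10⁻⁶ after 20 iterations). Pinning the diagonal re-injects
each patient's identity every step, exactly the role the diagonal plays in
the reference fusion algorithm, and the iteration then reaches a
structure-preserving fixed point (the convergence trace typically hits
machine zero within ~10 iterations).

The fused matrix (view average) is projected onto the symmetric
doubly-stochastic set by symmetric Sinkhorn scaling
(`S ← D^{−1/2} S D^{−1/2}`), so the exported network is simultaneously
symmetric and row-stochastic.

## Residual graph-convolutional branch

The branch runs on `Â = D̃^{−1/2}(A + I)D̃^{−1/2}` (self-loops + symmetric
normalization; spectral radius ≤ 1). Because residual addition needs equal
widths, the first layer is a non-residual projection of the concatenated
view features to the hidden width; blocks from layer 2 on compute
`H ← relu(Â H W + b) + H`, so a zero-weight block is exactly the identity.
The fusion module concatenates every block's output and applies one dense
layer; its activations are `F_PSN`. Defaults: 2 layers (deeper stacks are
supported and swept by `sweep_layers`), hidden and fusion width 64, dropout
0.5 on the fusion layer, Adam at 0.01 with weight decay 5 × 10⁻⁴, up to 300
epochs.

Two details proved essential at cohort sizes of a few hundred:

* **The PSN's diagonal is zeroed** (and rows renormalized) before the
  branch. `Â = A + I` assumes a self-loop-free adjacency; the fused
  network's dominant diagonal (≈ 1/2 by construction) otherwise swamps
  neighbourhood mixing and the branch degenerates into a row-wise MLP that
  memorizes the training mask (observed: train accuracy 1.0, test 0.64).
* **Early stopping on a held-out fifth of the training patients**
  (patience 20–30). The branch is transductive and trained features are
  in-sample; without early stopping they become label-perfect on training
  rows, and the downstream meta-learner overweights them.

## Per-view convolutional branches

Each view gets: 1-D convolution with same-padding (32 filters, kernel 5 by
default; the kernel shrinks to the view width for narrow views such as
clinical panels) → flatten → dense layer of 150 units (the specificity
features) → 2-class output. Kernels and dense weights are
glorot-initialized; dropout 0.5 on the dense layer and an L2 penalty of
10⁻⁴ regularize training (Adam, 10⁻³, 100 epochs). All forward passes are
deterministic at inference and row-wise independent.

Both neural branches are compact numpy implementations with analytic
gradients (verified against finite differences in the test suite) and an
Adam optimizer; training is full-batch and bit-reproducible under a fixed
seed.

## Stacking and the boosted forest

Feature blocks are concatenated in the fixed order PSN, Clin, Expr, CNV.
The meta-learner is discrete AdaBoost whose base learner is a small random
forest: 50 boosting rounds of 10 trees. Base trees are **depth 2**: with
depth-3 forests the base learner reaches zero weighted training error on
separable stacked features, which terminates discrete boosting after a
single round and collapses the ensemble to one small forest; depth-2 bases
stay weak, so boosting genuinely reweights (~30–50 rounds in our studies).
Prediction scores are the boosting-weight-weighted average of each base
forest's class-1 tree-vote fraction — a vote fraction in [0, 1] that is
smooth enough for rank-based metrics — thresholded at 0.5.

## Evaluation protocol

Stratified k-fold assignment is a deterministic partition (fold sizes
differ by ≤ 1, class counts balanced per fold; stratification can be turned
off). Per fold: mRMR on training patients → SNF over **all** patients →
ResGCN with the loss masked to training patients → CNNs on training rows →
AdaBoostRF on training rows → metrics on the held-out fold. Metrics are
averaged across folds, never pooled. AUC counts tied positive/negative
scores as 1/2; metrics with zero denominators report 0 with a warning
rather than aborting a fold. The log-rank p-value uses the 1-df chi-square
distribution. The 2-D embedding is t-SNE with perplexity
`min(30, (n−1)/3)`, deterministic given its seed.

The transductive protocol means test patients' *features* (never labels)
participate in graph construction and propagation, as is standard for
semi-supervised graph models; fully inductive variants are out of scope.

## Synthetic cohorts

The generator emulates the *shape* of a breast-cancer multi-omics cohort,
not its content. Defaults: 200 patients; 33 clinical features (24 discrete,
9 continuous), 60 expression, 40 CNV; 6/12/10 informative columns per view
carrying a class-conditional mean shift of 2 noise SDs; 40% of the
informative-signal variance shared across views through a common latent
factor; 25% long-term survivors (matching the imbalance typical of 5-year
breast-cancer cohorts); 5% missing clinical cells; 15% independent uniform
censoring (so censored-before-60-month patients exist and exercise the
exclusion rule). Survival times are exponential within class,
rejection-sampled to respect the 60-month boundary. CNV columns are
quintile-discretized after signal injection.

What the generator does **not** model: real marginal distributions, gene
identities, batch effects, informative censoring, nonlinear or interaction
signals. Passing tests therefore establish mechanical and statistical
correctness of the pipeline, not clinical performance.

## Study conditions and problem sizes

The end-to-end studies (test suite and `scripts/acceptance.py`) run at desk
scale: 200-patient cohorts; branch sizes hidden/fusion 32, 8 filters, 32
dense units, 200/40 epochs; mRMR keeps 20 expression and 15 CNV features
(mirroring, at this scale, the selection of a small informative subset from
each high-dimensional view). Signal-recovery studies use per-view signal
2.0 and 10-fold CV (5 seeds, mean AUC ≥ 0.9 expected; measured ≈ 0.96);
null studies use signal 0 (held-out AUC ≈ 0.5). The ablation and
single-view studies use per-view signal 1.0 — below saturation, since at
signal 2.0 every variant exceeds AUC 0.95 and component differences vanish
into ceiling noise — with 12 cohort replicates and 3-fold CV.

## Known limitations

* The full-model-vs-no-graph-branch margin is small at these cohort sizes
  (paired mean AUC difference ≈ +0.007 ± 0.006 over 12 replicates): the
  stacked architecture feeds the meta-learner in-sample branch features, an
  optimism that early stopping mitigates but does not remove, and at a few
  hundred patients the graph branch's unique contribution is modest. Seeds
  exist where removing it ties or marginally wins.
* Score calibration is not attempted; scores are vote fractions, not
  probabilities.
* Hyperparameters of the branches are sensible defaults, not tuned optima;
  the sweep harnesses (`sweep_layers`, `sweep_features`) exist for exactly
  that exploration.
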