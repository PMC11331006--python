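# msfn — multi-omics stacked fusion network for survival classification

`msfn` classifies cancer patients into long-term (≥ 5-year) and short-term
survivors from three omics views — clinical covariates, gene expression and
discretized copy-number variation — by fusing two complementary kinds of
prognostic information:

* **correlation information across patients and views**, captured by a
  patient similarity network (PSN) built with similarity network fusion
  (SNF) and mined by a residual graph-convolutional network (ResGCN);
* **specificity information within each view**, captured by one small
  1-D convolutional network (CNN) per view.

The hidden representations of all branches are stacked column-wise,

```
F_stacked = F_PSN ⊕ F_Clin ⊕ F_Expr ⊕ F_CNV ,
```

and an AdaBoost ensemble of small random forests (AdaBoostRF) is trained on
`F_stacked` to produce the final survival prediction.

## Model

**Patient similarity network.** For each view, patient affinities are

```
W_ij = exp( −d²(x_i, x_j) / (λ ε_ij) ),
ε_ij = ( mean_kNN_dist(i) + mean_kNN_dist(j) + d(x_i, x_j) ) / 3 ,
```

with `d` the Euclidean distance. `W` is normalized into a transition matrix
`P` with diagonal 1/2 and off-diagonal mass 1/2, and a sparse local kernel
`L` keeps each patient's `k` strongest neighbours. Cross-diffusion

```
P(v) ← L(v) · ( Σ_{u≠v} P(u) / (m−1) ) · L(v)ᵀ
```

iterates until the views agree; the fused network `S` (symmetric,
row-stochastic) is the mean of the converged views.

**ResGCN branch.** With self-loops and symmetric degree normalization,
`Â = D̃^{−1/2}(A + I)D̃^{−1/2}`, each residual block computes

```
G(N+1) = σ( Â · G(N) · W(N+1) ) + G(N) ,
```

a fusion layer over the concatenated block outputs yields `F_PSN`, and a
linear head produces the 2-class logits. Training is transductive
(all patients propagate; only training patients enter the loss).

**Per-view CNNs.** input → 1-D convolution with same-padding →
flatten → dense layer (the specificity features) → 2-class output, with
glorot initialization, dropout and an L2 penalty.

**Evaluation.** Stratified 10-fold cross-validation; AUC, accuracy,
precision, recall, F1 and Matthews correlation computed per fold then
averaged. Kaplan–Meier curves with a log-rank test and a 2-D t-SNE
embedding visualize the predictions.

## Worked example

Cohorts with known ground truth come from the built-in generator (three
views, class-conditional mean shifts, censored survival times):

```bash
msfn run --config configs/demo.yaml
```

runs the full pipeline on a 200-patient synthetic cohort under 10-fold
cross-validation and prints the per-fold metric table:

```
       accuracy  precision  recall        f1       mcc       auc   tp   fp    tn   fn
fold0  0.944444   0.800000   1.000  0.888889  0.861892  0.964286  4.0  1.0  13.0  0.0
...
fold9  0.764706   0.500000   0.750  0.600000  0.460882  0.942308  3.0  3.0  10.0  1.0
mean   0.915033   0.893333   0.815  0.831465  0.794628  0.984505
```

Each row is one held-out fold (~17 patients, ~5 long-term survivors); the
`mean` row is the cross-validated performance — here the pipeline separates
long- from short-term survivors almost perfectly (AUC 0.98) because the
cohort carries a strong simulated signal. `msfn_out/` also receives
out-of-fold predictions, Kaplan–Meier curves of the predicted groups with
the log-rank test (`logrank.json`: chi-square 74.5, p ≈ 6e−18 for this run),
a t-SNE plot of the stacked features, and a `manifest.json` that reproduces
the run bit-for-bit.

Other entry points: `msfn simulate`, `msfn snf`, `msfn evaluate`,
`msfn ablate`, `msfn sweep-layers`, `msfn sweep-features` (see `--help`).

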