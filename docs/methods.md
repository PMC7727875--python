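# Methods

## Overview

`tpscore` scores annotated gene sets ("transcriptional programs") by how
much information a gene-set-specific low-dimensional manifold carries
about a per-cell outcome. The pipeline per gene set is: subset the raw
count matrix → unsupervised 2-D embedding → random-forest prediction of
the outcome from the 2-D coordinates → out-of-bag performance as the
relevance score. This document records the model, its assumptions, the
parameters that matter, and the design choices that were genuinely open.

## Count autoencoder

The default embedding is a denoising autoencoder trained directly against
raw counts under a zero-inflated negative-binomial (ZINB) observation
model, in the style of count autoencoders for scRNA-seq.

**Input.** Counts are size-factor-normalized, log1p-transformed and
z-scored per gene. Size factors s_j = total_j / median(total) are always
computed on the transcriptome-wide matrix, not the gene-set subset: a
cell's sequencing depth is a property of the whole cell, and estimating
it from 50 genes would confound depth with program activity.

**Architecture.** Dense layers of widths `hidden_layers` (default
(64, 2, 64); the three benchmark variants (4, 2, 4), (8, 4, 8),
(16, 8, 16) are selectable). Non-bottleneck hidden layers are dense →
batch normalization → ReLU. The bottleneck is a plain linear layer; its
activations are the manifold coordinates. A linear (rather than ReLU)
bottleneck was chosen so that a 2-D latent cannot lose a quadrant or die
at zero. Batch normalization matters empirically: without it the latent
of strongly informative gene sets under-separates the cell groups
(benchmark fraction-1 sets plateau near OOB 0.88 instead of ≈ 0.95).

**Decoder heads.** From the last hidden layer: mean μ = s_j · exp(·)
(clipped pre-activation), dispersion θ = softplus(·) + 10⁻⁴, dropout
π = sigmoid(·) (ZINB only; `noise_model="nb"` removes the head). The loss
is the negative ZINB log-likelihood of the raw counts.

**Training.** Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), batch size 32, 10%
validation split, up to 300 epochs. The learning rate halves when the
validation loss plateaus for 8 epochs; training stops after 15 epochs
without improvement and the best weights (with their batch-norm running
statistics) are restored. All gradients are hand-derived numpy and are
verified against central finite differences in the test suite, including
the batch-normalization path; the NB log-pmf is verified against
`scipy.stats.nbinom`.

**Determinism.** All stochasticity (init, validation split, batch order)
derives from one integer seed; training is single-threaded numpy, so a
fixed seed reproduces coordinates bit-exactly. Genes are sorted
lexicographically before training so the embedding does not depend on the
row order of the input.

## Alternative backends

PCA, tSNE and UMAP run on the same preprocessed (normalized, log1p,
z-scored) submatrix, directly — gene sets are small, so no PCA
pre-reduction is used for tSNE/UMAP. PCA is exactly deterministic;
tSNE/UMAP are deterministic given a seed (single-threaded). tSNE
perplexity is clamped to (n_cells − 1)/3 for small inputs.

## Relevance score

A 500-tree random forest predicts the outcome from the embedding
coordinates. For categorical outcomes the score is out-of-bag accuracy;
for continuous outcomes (pseudotime) "out-of-bag accuracy" is undefined,
and the standard out-of-bag R² of a random-forest regressor is used
instead — this is the one place the package interprets rather than
follows a stated convention, and it is deliberately prominent here. An
RBF-kernel SVM comparator is provided for benchmarking; SVMs have no
out-of-bag notion, so stratified 5-fold cross-validated accuracy is
substituted (categorical outcomes only).

Cells present in the counts but absent from the outcome are dropped
*before* embedding, so the manifold is learned on exactly the scored
cells. Scoring requires ≥ 50 shared cells. Per-gene-set seeds derive
deterministically from the master seed and the set name, making results
independent of collection order.

## Synthetic data generator

The simulator emulates the splat family of scRNA-seq count models:

1. gene base means g_i ~ Gamma(shape 0.6, rate 0.3);
2. library sizes L_j ~ LogNormal(loc 11, scale 0.2);
3. group assignment multinomial with `group_proportions`;
4. each gene is DE with probability `de_prob`; a DE gene receives a
   per-group factor exp(N(`de_factor_loc`, `de_factor_scale`)), inverted
   (1/f) with probability 0.5 for down-regulation;
5. expected expression λ_ij = per-group gene proportions × L_j;
6. counts ~ Poisson(λ · Gamma noise) with squared coefficient of
   variation `bcv_common`² (i.e. negative-binomial);
7. logistic dropout per entry: p = 1/(1 + exp(−`dropout_shape` ·
   (ln(λ+1) − `dropout_mid`))), applied to the pre-noise expected count.

Ground truth (DE flags, per-group factors, pre-dropout λ) is recorded.
Two presets encode the benchmark scenarios: `two_group` (500 genes ×
2,000 cells, two equal groups, de_prob 0.1, de_factor_loc 0.01,
dropout_mid 5, dropout_shape −1) and `four_group` (1,000 × 4,000,
proportions 0.1/0.2/0.3/0.4, dropout_mid 2). `de_factor_loc = 0.01`
interprets the stated "differential expression factor" as the log-normal
location parameter — the only factor-named knob in this parameterization —
with the scale left at its conventional default (0.4); both are exposed.

With dropout_mid 5 the logistic midpoint sits near the mean per-gene
expected count, so roughly half of even well-expressed entries are zeroed:
the global structure is deliberately subtle (a UMAP of all genes does not
separate the groups), and only targeted, gene-set-specific embedding
recovers it.

**What the generator does not emulate:** expression-outlier genes,
trajectories/paths, batch effects, or a mean-dependent BCV trend (the
biological coefficient of variation is constant). Passing benchmarks on
these simulations therefore demonstrates recovery of group-structured DE
signal under realistic dropout and depth variation, not robustness to
batch confounding or continuous differentiation topologies.

## Benchmark harness

`make_mixed_gene_sets` draws sets of `set_size` genes mixing truly DE
genes at nominal fractions (0, 0.2, 0.4, 0.6, 0.8, 1) with null genes,
`n_bootstrap` sets per fraction (10 by default → 60 sets; 5 → 30). The
realized fraction is exact, so `set_size × fraction` must be integral.
`set_size` defaults to 50 ≈ the expected number of DE genes in the
two-group preset; because the realized DE-gene count is binomial and can
fall below 50, `benchmark_set_size` clamps the size to the largest
multiple of 5 not exceeding the available DE genes (multiples of 5 keep
all canonical fractions integral).

`t_test_vs_random` compares relevance at a test fraction (default 0.2)
against fraction 0 with a one-sided two-sample t-test, Welch by default
(a pooled-variance option is exposed). If both groups have exactly zero
variance but different means the test is degenerate; the implementation
returns p = 0 (or 1) with an infinite statistic under an explicit
epsilon-variance convention, and errors if the means are also equal.

The acceptance script (`scripts/acceptance.py`) runs this protocol at
fractions 0, 0.2 and 1 with the default autoencoder pipeline (30 gene
sets, full 500 × 2,000 preset, 500-tree forests) — about 6 minutes on one
CPU. The problem sizes are the preset's own; nothing is subsampled.

## Signature-score comparator

For comparison with global-manifold methods, `signature_score` computes a
per-cell mean of (optionally signed) z-scored log-normalized member-gene
expression, and `geary_autocorrelation` evaluates 1 − Geary's C of that
score over a symmetrized unit-weight kNN graph (default k = 30) of an
embedding: values near 1 indicate a score that varies smoothly over the
manifold, near 0 a randomly scattered one. This is a didactic
re-implementation of the autocorrelation idea, not of any full package;
the exact neighbor weighting of published tools is not reproduced.

## Numerical choices and degenerate inputs

- θ is floored at 10⁻⁴; exponential/sigmoid pre-activations are clipped
  at ±15 to avoid overflow; likelihood logs carry a 10⁻⁸ epsilon.
- Biases of non-batch-norm layers initialize at 0.01, keeping ReLU units
  off their kink at initialization (exact-zero activations otherwise make
  the loss non-differentiable at the starting point).
- Genes with zero variance after normalization become all-zero columns
  (they carry no information but keep the gene-set dimensionality honest).
- Cells with zero counts inside a subset are retained; dropping them
  would misalign the embedding with the outcome vector.
- A non-finite training loss raises immediately with advice to lower the
  learning rate; batches of a single cell are skipped under batch
  normalization (undefined statistics).
- Integer counts are validated on input; values like 1.5 are rejected
  rather than rounded.

## Known limitations

- Training is CPU numpy; per-set wall time is seconds on benchmark-sized
  sets but grows with cells × genes. No warm-starting between gene sets
  (each set retrains from scratch by design, since the input genes
  change).
- Relevance scores come with no significance calibration beyond the
  benchmark t-test; a fraction-0-style empirical null is the recommended
  route if one is needed.
- The weak-signal regime (≈ 20% informative genes) is intrinsically
  marginal: which DE genes land in a bootstrap set dominates its score,
  so the benchmark t-test hovers near the significance boundary by
  construction.
- HDF5/H5AD ingestion is not implemented; inputs are MTX/CSV/GMT/TSV.
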