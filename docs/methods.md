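# Methods

## Model

The classifier is a feed-forward network whose first layer — the *pathway
layer* — has one node per gene set and is sparsified by a binary genes ×
pathways membership mask `M`: node `i` receives input only from the member
genes of pathway `i`. Masking is enforced by elementwise multiplication of
the first-layer weight matrix with `M` inside the forward pass. Because the
gradient of any forbidden weight is then identically zero and Adam's moment
estimates for it stay at zero, forbidden weights remain **exactly** zero
through training; this invariant is asserted, not assumed, throughout the
test suite.

The pathway-layer pre-activation `P_si = Σ_j g_sj W_ji + b_i` is recorded as
the *pathway index* of sample `s`; it is a purely linear summary, so any head
nonlinearity affects predictions but never the index. A ReLU is applied to
the pathway layer before the head. The head is a stack of dense ReLU layers
ending in one sigmoid unit; the default is `(128, 32, 1)`, and the small test
configurations use `(16, 1)`.

Assumptions: expression values are continuous and sample-wise standardized;
labels are binary with both classes present in any training fold; gene
symbols match the GMT collection's symbols exactly (case-sensitive, no alias
resolution).

## Data handling

*Standardization* is per sample over **all** measured genes (mean 0, sd 1,
`ddof=1`), performed before any pathway-based gene subsetting — so the values
a model sees do not depend on which collection is used. Subsetting after
standardization is deliberately not re-standardized, and a test asserts the
two orderings disagree, pinning the pipeline's order.

*Splits* are repeated stratified half-splits. Stratification cells are
(label × group) when per-sample group tags (project/tissue) exist, otherwise
label alone. Within each cell `floor(n/2)` samples go to train and the
remainder to test, so 19,131 samples (10,964 + 8,167) always produce
9,565 / 9,566. Splits are deterministic functions of one integer seed.

## Training

Binary cross-entropy minimized with Adam (default learning rate 1e-3, batch
size 32), implemented directly in numpy so runs are bitwise deterministic for
fixed seeds on a fixed platform. Early stopping monitors loss on a random
10% carve-out of the training fold with a configurable patience and restores
the best-validation parameters.

A caution documented from our own use: with very small training folds the
carve-out (~tens of samples) is noisy, and the restored "best" epoch can be
an early, undertrained one. The architecture-comparison and permutation
procedures below therefore run fixed-length training (no early stopping),
which is both more stable and exactly reproducible. `max_epochs=0` is a
supported no-op that returns the seeded initialization.

First-layer weights are initialized He-style per pathway column using the
column's in-degree, head layers He-style by fan-in; all initialization comes
from a single model seed, while batch order and the validation carve-out come
from the training-config seed.

## Null architecture and the collection screen

The *random-linked* mask conserves only the **total** number of gene→pathway
edges, placing them uniformly at random over all (gene, pathway) cells —
per-gene and per-pathway degrees are not preserved, and zero-degree rows or
columns are permitted in the null (biological masks, by contrast, may not
contain empty rows/columns). Uniformity over edge placements is verified
against exhaustive enumeration of the C(9,2) placements on a 3×3 grid.

The screen trains the biological mask once per collection and `n_null`
random-linked models (fresh mask seed each), then computes a one-sample
z-test `z = (acc_bio − mean(acc_null)) / sd(acc_null)` with the n−1 sd
convention and a one-sided upper-tail p (the hypothesis is that membership
structure helps; a two-sided variant is a flag). Comparisons between two
repeated-run accuracy lists use Welch's t-test.

## Attribution indices

The contribution index `G_j = |(1/N) Σ_s Σ_i g_sj W_ji|` takes the absolute
value **after** averaging over samples, so signed contributions that cancel
across samples yield 0 — a property pinned by a dedicated test. Because
masked weights are exactly zero, summing over all pathways equals summing
over containing pathways only, and a gene belonging to no pathway has index
exactly 0. Both indices scale linearly in the expression values (bias
excluded), and both are checked against explicit triple-loop oracles to
1e−10 on random fixtures. Gene ranking uses dense ranks on descending index;
top-fraction selection takes `floor(fraction · n)` genes with lexicographic
tie-breaking for determinism (1% of 5,796 → 57; 50% → 2,898).

Subset retraining restricts the dataset to a gene list, re-intersects the
collection with it (the model's inputs are the genes that remain members of a
surviving pathway), rebuilds the mask per split, retrains, and reports
per-split test accuracy.

## Label-permutation pathway significance

Observed statistic: per-pathway difference of class-mean pathway indices on
the training fold. Null: shuffle the training-fold labels (class counts
preserved), **retrain** a fresh-seeded model on the shuffled labels,
recompute indices and the difference; repeat `n_perm` times (default 1000;
tests and the acceptance script use 50 to stay within desk-scale runtimes).
Per pathway, `z = (observed − null_mean)/null_sd`, two-sided normal p
(one-sided available), Benjamini–Hochberg q across pathways, significance at
q < 0.05. A pathway with zero null sd gets p = 1 plus a warning rather than
an infinite z. A fast mode that trains once and only re-labels the index
matrix exists for exploration; it underestimates the null spread contributed
by refitting and is explicitly not the reference procedure.

Calibration was checked empirically: on a label-independent fixture with 100
pathways and 50 permutations, the fraction of pathways at p < 0.05 stays
within the binomial 95% band around 0.05 (the z-statistic uses an estimated
sd from 50 draws, so tails are very slightly heavy, consistent with a t(49)
reference).

## Synthetic fixtures

The generator targets the stage the model actually consumes: values on the
standardized scale, i.i.d. Gaussian per gene (`noise_sd`, default 1), binary
labels at `class_balance` (default 0.5), group tags cycling over four
pseudo-projects so stratified splitting is exercised. Class-1 samples get an
additive shift of `effect_size · noise_sd` on every gene belonging to a
designated signal pathway; the default planted effect is 1 sd, the package's
canonical detectable-but-not-trivial condition. A monotone positive-scale
wrapper emits log2(FPKM + 0.001)-shaped values for I/O tests.

Not emulated: count noise, gene–gene correlation beyond the shared class
shift, library-size/batch effects, tissue structure. Passing tests therefore
demonstrate the machinery's correctness and statistical behaviour under a
clean additive-shift model, not performance on real RNA-seq.

### Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale study conditions: planted-recovery
runs use 500 samples × 200 genes × 20 pathways with one 1-sd signal pathway,
80 training epochs and 50 permutations; the architecture comparison uses 400
samples × 200 genes × 20 pathways (8–15 genes each) with two signal pathways
and, per seed, averages 3 biological initializations against 5 random-linked
masks (at small n a single run's seed variance exceeds the architecture gap,
so the mean is the scaled-down estimator of the same directional quantity);
calibration uses 200 samples × 150 genes × 100 pathways with zero effect.

## Design choices where the design was open

- **Index definition**: the pathway index is the pre-activation value; the
  contribution index uses the full masked weight matrix (identical, by the
  mask-zero invariance, to a membership lookup — an equivalence that is
  itself tested).
- **sd convention**: n−1 everywhere (row standardization, accuracy reports,
  z-tests, permutation nulls).
- **Sidedness**: one-sided for the architecture screen (directional
  hypothesis), two-sided for pathway significance (either direction of class
  difference is interesting).
- **Random-linked nulls** conserve the total edge count only — the global
  definition, not a per-node degree-preserving rewiring.
- **Tie-breaks**: lexicographic gene symbols in top-k selection; mergesort
  (stable) in all table sorts.
- **Odd stratification cells** send the extra sample to test.

## Known limitations

- The numpy network is CPU-bound and single-threaded beyond BLAS; it is sized
  for thousands of genes × hundreds of pathways, not for very deep heads.
- Permutation significance retrains per permutation; 1000 permutations on a
  large dataset is hours of CPU. Checkpointing writes partial null tables so
  long runs can be inspected; the fast mode is a screening tool only.
- No gene-symbol alias resolution: mismatched symbol conventions silently
  shrink the intersected universe (the intersection report makes this
  visible).
- Exact accuracy values depend on the platform's floating-point behaviour
  only through BLAS reduction order; with the pinned numpy this is stable,
  but bitwise reproducibility across different BLAS builds is not guaranteed.
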