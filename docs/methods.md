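# Methods

## Coarse-graining

Droplet scRNA-seq counts are dominated by technical zeros, so pairwise
Pearson correlations computed on raw cells are mostly noise. We collapse
each neighborhood of transcriptionally similar cells into one super-cell
before estimating co-expression. The pipeline is: counts-per-10k
library-size normalization → log1p → truncated PCA (randomized solver,
default 25 components, capped at the data rank) → k-nearest-neighbor graph
(default k = 5), symmetrized as the union of directed neighbor relations →
short-random-walk (walktrap, 4 steps) community agglomeration, cut at the
dendrogram level whose group count is closest to `n_cells / gamma`.
Every count between the number of connected components and `n_cells` is
reachable on the merge path, so the cut is exact after clamping; groups
never span disconnected components, and singletons are permitted.
`gamma = 1` short-circuits to the identity partition.

Aggregation **sums** member-cell counts rather than averaging: sums keep
the count nature and total mass of the data (conservation is tested
exactly), and the downstream correlation normalizes per super-cell, so
group sizes cannot leak in.

Pooling only helps if neighboring cells share biological state — if cells
were i.i.d., pooling would shrink signal and noise equally. This is why
the synthetic generator (below) puts most activity variance on a latent
manifold; it is also the operating assumption for real data: within a
sample, cells occupy a low-dimensional state space.

## Network refinement

The three input networks (W⁰ motif prior, P⁰ PPI prior, C⁰ co-expression)
are each normalized to z-units as `(zrow + zcol)/√2` with sample standard
deviations; a zero-variance row or column contributes 0 for its term, so a
constant matrix maps to zeros. Per iteration: availability
`A = T_Z(W rows, C columns)`, responsibility `R = T_Z(P rows, W columns)`,
`W ← (1−α)W + α(A+R)/2`; then P and C move the same fraction toward
pairwise T_Z similarities of the **updated** W's rows/columns. The
all-zero-vector T_Z convention is 0 (no information, no similarity).

**Diagonal handling.** T_Z self-similarity grows with vector norm, so the
raw diagonals of the P/C updates would dominate and, left unchecked, the
three matrices feed back superlinearly and the iteration diverges (we
verified this directly: holding the diagonals fixed at their initial
values produces Hamming distances of order 10⁹ within 100 iterations on
10 × 40 instances). We therefore set each similarity matrix's diagonal to
`(off-diagonal row SD) · n · exp(2αt)` before blending. The exponential
growth makes each node's own message dominate the T_Z denominators as t
grows, which damps the effective updates and gives the scheme its
convergence: in practice the mean absolute change of W falls below the
0.001 default within ~25–30 iterations at α = 0.1 on all tested instances.

**Convergence criterion.** The continuous Hamming distance is the mean
absolute entrywise difference between successive W iterates, on W only —
W is the returned object, and defining the criterion on the other two
matrices would couple it to their (inflated) diagonals. Non-convergence at
`max_iter` (default 100) returns the last iterate with a warning, never an
error. α = 0 degenerates to a single step returning the normalized prior.

**Tunable parameters.** α = 0.1 (update fraction per iteration; smaller
values keep the result closer to the motif prior), tol = 0.001 (on the
z-score scale of W), gamma = 10 cells per super-cell, 25 embedding
components, 5 neighbors, min_cell_fraction = 0.05 (a gene must be nonzero
in at least 5% of cells). Genes additionally need at least one motif edge;
`keep_uncovered_genes=True` retains uncovered expressed genes with
zero-filled prior columns instead. The TF universe comes from the prior
alone — undetected TFs are still scored. The PPI diagonal is set to the
maximum observed PPI score (a TF maximally cooperates with itself); with
an empty PPI prior it is 1. Duplicate prior rows collapse to the maximum
score — for motifs this keeps the best match per promoter; we apply the
same rule to PPI edges for uniform deduplication semantics, symmetrizing
by the max over orientations.

All dense linear algebra happens on the aligned (coarse-grained) problem,
which is small; sparse storage is used only for raw counts.

## Population statistics

All networks are in z-units over aligned universes, so:

- **Paired comparison** (one TF, two conditions): deltas are
  `W_b[tf,·] − W_a[tf,·]` on the shared genes, tested with a one-sample
  two-sided t-test. The "95% interval" used for calling outlier genes is
  the 2.5–97.5 percentile band of the *empirical delta distribution* —
  a confidence interval on the mean could not label individual genes,
  which is the purpose of the call. Zero-variance deltas are reported as
  t = 0, p = 1.
- **Edge trends**: each shared edge's weight is regressed by OLS on an
  integer stage code (e.g. healthy 1 → metastasis 4); the slope β is the
  average rate of change per stage, its p-value comes from the regression
  F-test, and BH-FDR is applied across all edges jointly. Zero-variance
  edges get β = 0, p = 1 (no-evidence convention). The per-TF association
  score sums β over the TF's edges (all edges by default;
  `significant_only` restricts to BH-significant ones — the sum over all
  edges matches the definition of the targeting-change score and keeps
  the statistic linear).
- **Differential targeting**: Welch (unequal-variance) two-sample t-tests
  per TF on outdegrees, BH across TFs; Welch because group variances of
  outdegrees have no reason to be equal.
- **Preranked GSEA**: weighted Kolmogorov–Smirnov running sum with weight
  exponent 1; the null is gene-label permutation (random same-size sets),
  since phenotype permutation is undefined for a single ranking. NES
  divides ES by the mean |ES| of same-sign permutations; the p-value is
  the two-sided empirical tail on |ES| with the +1 correction, BH-adjusted
  per collection. Sets with fewer than 3 ranked members are skipped with
  a warning. Deterministic given the seed.

BH-FDR is delegated to statsmodels but is cross-checked in the test suite
against a brute-force step-up computation at 1e-12.

## Synthetic data

The generator plants a sparse signed TF → gene weight matrix (Bernoulli
support at the requested density, default 0.1; magnitudes uniform in
[0.5, 2]; 70% activating) and drives expression through latent TF
activities:

- log-activities are Gaussian with SD `noise_sd = 1.2` (≈3–10× activity
  range across cells, typical of regulon activity across cell states);
  a `state_share = 0.8` fraction of that variance is shared along a
  `latent_dim = 6` dimensional cell-state manifold whose TF loadings are
  drawn once per truth (replicates share the same biology). The manifold
  is essential: it is what makes kNN super-cell pooling average noise
  rather than signal.
- gene rates are `softplus(activity @ W)` — softplus rather than exp so
  rates cannot blow up at desk scale — modulated by gamma noise with
  `overdispersion = 0.15` (gamma-Poisson, i.e. negative-binomial counts;
  without overdispersion, unexpressed genes in a small gene universe stay
  spuriously correlated through the shared library-fraction denominator),
  rescaled per cell to a lognormal library (median 5,000 counts, σ = 0.3),
  Poisson-sampled, then thinned by Bernoulli dropout (default 60%).
- perturbations act on latent activity — knockout zeroes the TF,
  overexpression multiplies it (default factor 2) — never on the priors,
  matching how perturbation experiments are analyzed.
- priors derived from the truth: `exact` (binarized support), `noisy`
  (independent flip rates), and `randomized` (degree-preserving
  checkerboard shuffle — the standard negative control).
- `plant_master_regulator` turns one TF into a dominant activator
  (program over 25% of genes, 90% of those targets exclusive to it, drawn
  on its own private activity axis), the regime that knockout /
  overexpression studies deliberately target.

What the generator does **not** emulate: batch structure, doublets,
UMI saturation, gene-length effects, discrete cell types (the manifold is
continuous), or TF–TF cooperativity (hence simulation experiments use an
empty PPI prior — self-cooperation only). Passing tests therefore show
correctness of the machinery and qualitative behavior under a plausible
generative model, not performance on any particular tissue.

## Behavior under strong perturbations — a caveat

On prior-supported edges the perturbation response is robust and has the
expected direction: knocking out a master regulator lowers its supported
edge weights by ≈1 z-unit at the default simulation scale, and
overexpression raises them; unperturbed TFs move an order of magnitude
less. The **all-gene mean** of the perturbed TF's row is a different
matter: z-normalization of C ties the availability of *uncovered* genes
to the global co-expression context, so covered and uncovered genes move
in opposite directions with near-conservation of the row mean. At desk
scale (hundreds of genes, prior coverage ≤ 30%) the uncovered-gene
rebound can dominate the row mean and flip its sign relative to the
covered-edge response. The paired-comparison report therefore exposes
both the full-row mean and the supported-edge mean; for interpreting
perturbations, the supported-edge statistic is the meaningful one.
The acceptance checks report both.

## Numerical choices

- Sample (ddof = 1) standard deviations throughout the z-normalization.
- Network files store weights at 17 significant digits and are re-read
  with correctly-rounded float parsing, so write → read is bit-exact.
- Writes are atomic (temp file + rename): a failed write leaves no
  partial file.
- Ties in the GSEA ranking are broken by gene label for determinism.
- AUROC/AUPRC are computed on |weight|, because refined weights are
  signed z-units while planted support is binary.
- Walktrap, neighbor search, and the randomized PCA solver are all
  deterministic given the seed; the whole pipeline is bit-stable
  (asserted in the tests).

## Validation problem sizes

The standard validation conditions are 20 TFs × 200 genes × 2,000 cells
at 60% dropout, gamma = 10, α = 0.1, tol = 0.001; recovery and
concordance experiments use seeds 0–2, calibration experiments use 2,000
null edges × 40 networks and 200 GSEA draws at 200–1,000 permutations.
These sizes were chosen so the full validation runs in well under a
minute on one core while leaving the statistical assertions comfortable
margins.
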