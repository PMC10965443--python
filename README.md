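# scorpion-grn

Single-cell RNA-seq data are too sparse for reliable gene–gene correlation
estimates, which is what most gene regulatory network (GRN) inference
methods feed on. This package infers **comparable, per-sample TF × gene
regulatory networks** from single-cell counts by (1) coarse-graining
similar cells into *super-cells* to beat dropout, then (2) refining a
motif-based regulatory prior with protein–protein-interaction (PPI) and
co-expression evidence through iterative message passing. Because every
network lives in the same z-score units over the same TF/gene universes,
networks from different samples can be compared with ordinary statistics —
paired edge tests, per-edge trend regression over disease stages,
differential TF targeting, and edge-ranked gene-set enrichment — all of
which ship here too.

It is written for computational biologists studying regulatory differences
across conditions, stages, or perturbations at the sample level.

## The model

Three networks are refined jointly:

- **W** (TF × gene): the regulatory network, seeded from motif-footprint
  scores in promoter regions (W⁰);
- **P** (TF × TF): cooperativity, seeded from PPI scores;
- **C** (gene × gene): co-regulation, seeded from Pearson co-expression of
  coarse-grained profiles.

All three are first normalized to z-scores, entry (i,j) ↦
(z_row + z_col)/√2. Each iteration computes, for every TF i and gene j,

- availability  A_ij = T_Z(W_i·, C_·j)  — agreement between the TF's
  targeting profile and the gene's co-expression profile, and
- responsibility R_ij = T_Z(P_i·, W_·j) — agreement between the TF's
  cooperativity profile and the gene's regulator profile,

where T_Z is a continuous Tanimoto similarity

```
T_Z(x, y) = Σᵢ xᵢyᵢ / sqrt(Σᵢ xᵢ² + Σᵢ yᵢ² − |Σᵢ xᵢyᵢ|).
```

W then moves a fraction α toward (A + R)/2:

```
W ← (1 − α)·W + α·(0.5·A + 0.5·R),       α = 0.1 by default,
```

and P and C move the same fraction toward pairwise T_Z similarities of
W's rows and columns. Iteration stops when the mean absolute change of W
(a continuous Hamming distance) drops below 0.001 (default). The returned
matrix has TFs in rows, genes in columns; values are signed z-units.

Genes enter the model if they are expressed in ≥ 5% of cells and carry at
least one motif edge; TFs enter from the prior alone, so the activity of
transcription factors the assay never detected is still quantified.

## Worked example

```python
from scorpion import (SimulationConfig, generate_truth, simulate_counts,
                      corrupt_prior, empty_ppi_prior, ScorpionGRN,
                      evaluate_recovery, degrees)

config = SimulationConfig(seed=0)          # 20 TFs x 200 genes x 2,000 cells
truth = generate_truth(config)
expr = simulate_counts(truth, config)      # sparse counts, 60% dropout
motif = corrupt_prior(truth, "exact")      # binarized truth support as prior

grn = ScorpionGRN(gamma=10, random_state=0)
grn.fit(expr, regulatory_prior=motif, ppi_prior=empty_ppi_prior())
print(f"converged in {grn.n_iter_} iterations "
      f"(final Hamming distance {grn.hamming_history_[-1]:.2e})")
auroc, auprc = evaluate_recovery(grn.to_network(), truth)
print(f"planted-edge recovery: AUROC {auroc:.3f}, AUPRC {auprc:.3f}")
print(degrees(grn.network_, "outdegree").sort_values(ascending=False).head(3))
```

prints

```
converged in 24 iterations (final Hamming distance 8.58e-04)
planted-edge recovery: AUROC 1.000, AUPRC 1.000
TF010    32.120216
TF009    30.052709
TF012    20.831911
dtype: float64
```

The refinement converged below the 0.001 tolerance in 24 sweeps; ranking
all TF–gene pairs by |weight| separates the planted edges from the
non-edges perfectly (AUROC/AUPRC = 1.0 with the exact prior); and the
outdegree (row sum) ranks TFs by total targeting activity.

The same pipeline is available from the shell:

```
scorpion simulate --genes 200 --tfs 20 --cells 2000 --seed 0 -o sim/
scorpion build --counts sim/ --motif sim/motif_prior.tsv --ppi sim/ppi_prior.tsv -o net.tsv
scorpion compare net_a.tsv net_b.tsv --tf TF009 -o report.md
scorpion trend --networks list.tsv -o trend.tsv
scorpion targeting --group-a a1.tsv --group-a a2.tsv --group-b b1.tsv --group-b b2.tsv -o targeting.tsv
```

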