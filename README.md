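# gxede

Factorial (genotype × environment) differential-expression analysis with
empirical-Bayes moderated t-statistics, plus cross-comparison set-logic
classification of every gene.

`gxede` is built for two-dimensional comparative transcriptomics
experiments: two genotypes (a wild type and a knockout of a regulator)
assayed in two environments (e.g. ground control versus spaceflight), with
a handful of biological replicates per group. From a summarized gene ×
sample expression table it answers two questions at once:

1. **Vertical:** which genes does each genotype differentially express
   between the two environments (its *physiological adaptation*)?
2. **Horizontal:** which genes distinguish the genotypes within each
   environment (the *ground-* and *environment-adapted states*)?

and then combines the four comparisons to classify each gene by *which
genotype had to adjust its expression to reach the adapted state* —
the interesting biology when the knockout removes a regulator whose role
in the new environment is unknown.

## The model

Expression is analyzed on the log2 scale with a cell-means linear model per
gene *g*: one mean per genotype × environment cell and a single pooled
residual variance s²_g on d_g = N − 4 degrees of freedom. Gene-wise
variances are assumed exchangeable with a scaled inverse chi-square prior

    σ²_g ~ d₀·s₀² / χ²_{d₀}

whose parameters (d₀, s₀²) are estimated from all genes by matching the
first two moments of log s²_g through the digamma/trigamma functions. Each
contrast is tested with the moderated t-statistic

    t̃_g = (ȳ₁ − ȳ₂) / √( s̃²_g (1/n₁ + 1/n₂) ),
    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),

referred to a t distribution on d_g + d₀ df, with Benjamini–Hochberg FDR
correction across genes. A gene is called up/down in a comparison when
p < 0.01 (BH-adjusted by default) **and** |log2FC| > 1, both strict.

The four per-gene calls — `(WT flight vs ground, KO flight vs ground,
KO vs WT ground, KO vs WT flight)` — are then classified:

| category | pattern (vertical WT, vertical KO, ground, flight) |
|---|---|
| `shared_same` / `shared_opposite` | both verticals significant, same / opposite sign |
| `required` | WT responds; genotypes differ on the ground; KO does not respond; genotypes match in the new environment |
| `corrected` | mirror image: only KO responds, and corrects to the WT level |
| `genotype_dependent` | only WT responds; difference appears only in the new environment |
| `compensated` | only KO responds; difference appears only in the new environment |
| `persistent_genotype_difference` | genotypes differ the same way in both environments |

A Fisher-exact (hypergeometric upper-tail) enrichment module tests
user-supplied term annotations (GMT-style file) for over-representation in
any gene list against a background, with a minimum-mapping filter and no
multiplicity adjustment by default. A synthetic-data generator plants each
category's canonical effect pattern with known ground truth, so the whole
pipeline is testable end to end without any array data.

## Worked example

```python
from gxede import SimulationConfig, ThresholdConfig, analyze, simulate_dataset

config = SimulationConfig(n_genes=2000, seed=1)   # plants 20 genes/category
matrix, truth = simulate_dataset(config)
fits, moderation, results, assignments, summary = analyze(matrix, ThresholdConfig())

print(f"variance prior: d0 = {moderation.prior_df:.2f}, s0^2 = {moderation.prior_var:.4f}")
print(summary.to_string(index=False))
```

prints

```
variance prior: d0 = 3.93, s0^2 = 0.0494
                         entry       kind  significant   up down
           WT_flight_vs_ground comparison           79   79    0
           KO_flight_vs_ground comparison           78   57   21
               KO_vs_WT_ground comparison           59   39   20
               KO_vs_WT_flight comparison           76   35   41
                   shared_same   category           19 <NA> <NA>
               shared_opposite   category           20 <NA> <NA>
                      required   category           20 <NA> <NA>
                     corrected   category           20 <NA> <NA>
            genotype_dependent   category           20 <NA> <NA>
                   compensated   category           17 <NA> <NA>
persistent_genotype_difference   category           18 <NA> <NA>
                 other_pattern   category            4 <NA> <NA>
                          none   category         1862 <NA> <NA>
```

The estimated variance prior (d₀ ≈ 3.9, s₀² ≈ 0.049) recovers the
generator's d₀ = 4, s₀² = 0.05. The simulator planted 20 genes per
category at a 2 log2-unit effect; 134 of the 140 are recovered in their
intended category (the rest fall just below a significance gate in one of
their four comparisons). Per-comparison counts are consistent by
construction: `up + down = significant`.

The same analysis is available from the shell:

```bash
gxede simulate --n-genes 2000 --seed 1 --out-dir sim/
gxede run-all --expression sim/expression.tsv --meta sim/samples.tsv \
      --input-scale log2 --out-dir results/
gxede verify-knockout --expression sim/expression.tsv --meta sim/samples.tsv \
      --gene G000001
```

`run-all` writes one DE table per comparison
(`gene_id, log2FC, t_mod, p_raw, p_adj, status`), a per-gene category table,
a count summary and a run log.

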