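# repclone

Clonotype-level analysis of T-cell receptor β-chain (TRB) CDR3 repertoires
from paired tissue compartments — built for the question of whether memory
T-cell subsets in a tissue (e.g. human lung) and its draining lymph node
(LDLN) descend from shared or separate progenitor pools.

Intended users are computational immunologists working with bulk TCR-seq /
RNA-seq-derived clone tables (MiXCR- or AIRR-style exports) sorted into
CD4/CD8 naive, central-memory (CM), effector-memory (EM) and
tissue-resident-memory (TRM) populations from two sites of several donors.

## What it computes

A *clonotype* is a set of cells with an identical CDR3 nucleotide sequence;
reads are collapsed on that key after discarding nonproductive
rearrangements (out-of-frame, or a stop codon in frame 0). On the collapsed
repertoires the package provides:

- **Diversity** — clonality `1 − H/ln S` (1 − Pielou evenness of clone
  frequencies) and exact hypergeometric rarefaction
  `E[S_m] = Σ_i [1 − C(N−n_i, m)/C(N, m)]`.
- **Clonal overlap** — sample × clonotype frequency matrices restricted to
  clonotypes present in ≥ 2 samples (or ≥ 2 subsets of one donor), donor
  inclusion rules (≥ 3 CD4 subsets per tissue, > 150 shared clonotypes),
  and ranking of the most-shared clones for heatmap display.
- **Tissue concordance** — per-donor agglomerative clustering of subsets on
  Euclidean distances between shared-clone frequency vectors; the tree is
  cut into two clusters, each memory subset is scored against its cluster's
  majority tissue, and pooled tallies get an exact two-sided binomial test
  against chance: `P = Σ_{i: pmf(i) ≤ pmf(k)} C(n,i)/2^n`.
- **Pooled MDS** — classical (Torgerson) scaling of all samples on one
  common distance scale, per-donor averaged distance groups
  (naive↔memory per tissue, within-tissue memory, cross-tissue identical
  subsets), and Wilcoxon rank-sum comparisons of the per-donor averages.
- **V-J usage bias** — each clonotype counted once regardless of expansion,
  pooled once per donor; Pearson residuals `(obs − exp)/√exp` and exact
  binomial p-values against a uniform (or margin-product) null flag over-
  and under-used segments.
- **Synthetic cohorts** — a seeded generator of multi-donor two-tissue clone
  tables with controllable within-tissue/cross-tissue sharing, power-law
  clone sizes, near-private naive repertoires and plantable V/J usage bias,
  so every analysis is testable end to end without external data.

## Worked example

```sh
$ python examples/06_full_pipeline.py
```

```
16 artifacts written to scratch/example_run

repclone 0.1.0 run summary
  input rows: 21919; productive: 21919 (removed 0)
  samples: 24; unique clones: 19872 (5.9% in >1 sample)
  donors included: 3 (D01, D02, D03)
  tissue concordance: 18/18 memory subsets (binomial P = 7.63e-06)
  MDS group distance medians: cross_tissue_identical=0.00307, naive_vs_memory_ldln=0.0265, naive_vs_memory_lung=0.0315, within_ldln_memory=0.00182, within_lung_memory=0.00241
  V segments over-represented (pooled): V20-1, V5-1, V7-2
```

Reading it: only ~6% of clonotypes recur in more than one sample, yet every
memory subset clusters with its tissue of origin rather than with its
phenotype (18/18; chance would be ~9), and cross-tissue distances between
phenotypically identical subsets exceed within-tissue distances between
different subsets — the signature of largely separate progenitor pools per
tissue. The flagged V segments are exactly the ones the generator
over-weights.

The `examples/` directory has one short script per capability; each builds
a small synthetic input, runs one analysis and prints annotated numbers.

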