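# paleoreg

Tools for finding genes under putative modern-human-specific regulation:
enhancers and promoters active in the developing cortex that carry derived
single-nucleotide changes (SNCs) on the modern human lineage — at fixed or
≥90% derived-allele frequency — while Neanderthals/Denisovans retain the
ancestral allele, together with the downstream statistics such a screen
needs. The package is aimed at comparative/regulatory genomicists who want
the full procedure as tested, reusable code, with a synthetic-data module
that generates every input with planted ground truth so each stage can be
validated end to end.

## What it computes

**Candidate selection.** Each regulatory region *r* is annotated with the
modern and archaic SNCs it contains; *r* is a candidate iff
`n_modern(r) ≥ 1` and `n_archaic(r) = 0` (depletion filter). An adult
enhancer additionally passes only if it is completely contained in an
H3K27ac peak with no H3K4me3 overlap (active-enhancer, promoter-free
signal). Genes are resolved through a region→gene linkage table (Hi-C
derived, consumed as TSV) and classified by whether a linked enhancer
and/or promoter carries a *fixed* mSNC (frequency ≥ 1 − ε, default
ε = 10⁻⁶).

**Mutation-density ranking.** For regions of ≥1000 bp, density = mSNC
count / length; the top 5% per class (`⌈0.05·n⌉`, deterministic
tie-breaking) are flagged.

**Region-set enrichment.** Permutation test: the observed number of query
regions overlapping ≥1 feature region (sweep regions, disease loci) is
compared to `n_perm` length-preserving uniform re-placements;
`p = (b+1)/(n_perm+1)`, plus a z-score against the permutation null.

**Gene-set and motif enrichment.** Upper-tail hypergeometric tests,
`P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`, BH-corrected; PWM scanning with
log₂-odds scores on both strands at a per-window p-value threshold computed
exactly by dynamic programming, and a hypergeometric test of binary motif
hits in targets vs a background sequence set.

**Co-expression modules.** Single-cell QC (≥500 detected genes/cell, genes
in ≥10% of cells, 2000–9000 total counts, ≤5% mitochondrial), LogNormalize
(scale 10⁶), cell-cycle scoring and covariate regression, then a signed
weighted network: biweight midcorrelation, adjacency
`a_ij = ((1+cor_ij)/2)^β`, topological overlap matrix (TOM), and module
detection on 1 − TOM by average-linkage clustering (minimum module size
200), intersected with the candidate gene list.

## Worked example

```python
from paleoreg.simulate import (DEFAULT_GENOME, simulate_regions, simulate_sncs,
                               simulate_feature_sets)
from paleoreg.filters import (annotate_regions, select_candidates,
                              resolve_gene_list, classify_fixed_genes)
from paleoreg.density import mutation_density, top_fraction
from paleoreg.enrichment import permutation_overlap_test

regions, linkage = simulate_regions(rng_seed=1)      # 300 enhancers + 200 promoters
sncs, truth = simulate_sncs(regions, rng_seed=2)     # planted lineage-specific changes

candidates = select_candidates(annotate_regions(regions, sncs))
genes, evidence = resolve_gene_list(candidates, linkage)
enh_fixed, prom_fixed, both = classify_fixed_genes(evidence)

ranked = top_fraction(mutation_density(annotate_regions(regions, sncs)), fraction=0.05)
sweeps = simulate_feature_sets(DEFAULT_GENOME, candidates, rho=0.5, rng_seed=3)
res = permutation_overlap_test([r.interval for r in candidates], sweeps,
                               DEFAULT_GENOME, n_perm=10_000, rng_seed=4)
```

Output (seeds as above):

```
candidate regions: 155 (88 enhancers, 67 promoters)
linked genes: 215; fixed changes in enhancers: 103, promoters: 87, both: 24
exact recovery of planted truth: True
density ranking: 18 of 339 eligible regions in the top 5%
sweep-region overlap: observed 43, null 26.3 +/- 4.7, p = 4.00e-04, z = 3.52
```

Of the 500 simulated regions, 155 pass the harbor-mSNC/archaic-depleted
filter and exactly match the generator's planted candidate set; the
region→gene join yields 215 genes, of which 24 have fixed changes in both
an enhancer and a promoter. With half of the 50 simulated sweep-scale
features forced onto candidates, 43 candidates overlap a feature where the
permutation null expects ~26, giving p = 4×10⁻⁴ (10,000 permutations).

A `paleoreg` console script exposes the same stages
(`simulate`, `filter`, `rank`, `enrich-overlap`, `enrich-genes`, `motif`,
`coexpress`); run `paleoreg --help`.

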