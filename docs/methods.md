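# Methods

This note documents the models and procedures implemented in `paleoreg`,
the parameter defaults and why they were chosen, the design decisions taken
where more than one reading was defensible, and what validation on
synthetic data does and does not establish.

## Coordinates and inputs

All internal coordinates are 0-based half-open (BED convention). SNC
catalogs report 1-based positions (VCF/catalog convention) and are
converted on ingest; a position *p* becomes the interval `[p−1, p)`.
Chromosome names are compared as exact strings after optional stripping of
a `chr` prefix, since region files and variant catalogs commonly mix the
two conventions. Zero-length intervals are rejected on read: their overlap
semantics are undefined. Genome assemblies are labels only — no sequence
is read outside the motif module, whose sequences arrive as FASTA keyed by
region id.

## Candidate selection

An SNC is *modern* if the derived allele arose on the modern-human branch
(archaic genomes ancestral) and *archaic* in the converse case. Modern
SNCs carry a derived-allele frequency in present-day humans; *fixed* means
frequency ≥ 1 − ε with ε = 10⁻⁶ by default. Because upstream catalogs
typically publish discrete classes ("fixed" vs "≥90%") rather than exact
frequencies, ingest also accepts an explicit per-record fixed flag that
overrides the frequency rule.

A region is a candidate iff it contains ≥1 modern SNC and exactly 0
archaic SNCs, at any frequency — depletion is absolute because no
threshold is defensible a priori. The adult-enhancer filter keeps an
enhancer iff it is completely contained in at least one H3K27ac peak that
itself has no H3K4me3 overlap; the disqualification is applied at the peak
level by default, with an `enhancer`-level mode for the alternative
reading (the phrasing of the source protocols is ambiguous between the
two). Gene resolution takes the union of linked genes over candidate
regions (a gene qualifies if ≥1 of its linked regions is a candidate);
candidates missing from the linkage table are excluded with a logged
warning rather than an error, since linkage tables are routinely
incomplete.

## Mutation-density ranking

Density = modern-SNC count / region length, computed only for regions of
at least 1000 bp (shorter regions make the ratio unstable). The flagged
set is the top 5% by density *within each region class*, with
`⌈fraction·n⌉` so that a small class still yields at least one candidate.
Ties at the boundary are broken deterministically: longer region first,
then lexicographic region id — the choice is arbitrary but reproducibility
requires one. A `fixed_only` switch restricts the numerator to fixed
changes; the default counts fixed plus nearly fixed.

## Permutation region-set enrichment

The statistic is the number of query regions overlapping ≥1 feature region
(binary per-region overlap, the conventional default for region-set
enrichment, rather than total overlap events). The null is built by
re-placing the query set: each region keeps its length, and its new
location is uniform over all valid placements genome-wide — equivalently,
the chromosome is drawn with probability proportional to
`chrom_length − region_length + 1` and the start uniformly among valid
positions. For regions much shorter than chromosomes this is
indistinguishable from length-proportional chromosome assignment, and it
makes the uniform-start property exact for long regions too. No
masking/gap handling is implemented: the toy genomes the pipeline is
validated on have none.

The empirical p-value is `(b+1)/(n_perm+1)` with `b` the number of
permutations at least as extreme as the observation, so p is never 0 and
never below `1/(n_perm+1)`. A z-score against the permutation mean/SD is
reported alongside. Default `n_perm` is 10,000 for single analyses;
replicated calibration experiments use 1000 to stay within desk-scale
runtimes.

## Gene-set and motif enrichment

Gene-set over-representation is the upper-tail hypergeometric probability
`P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, against a user-supplied universe,
corrected across terms by Benjamini–Hochberg. The graph-structured
multiple-testing scheme some enrichment servers use is deliberately not
reimplemented — it is tied to a specific ontology topology — and the
output labels the correction `bh` to make the substitution explicit.

PWMs (JASPAR-style text, counts or probabilities) are pseudocount-smoothed
(10⁻⁴) and scanned on both strands with the log₂-odds score
`Σ log2(p_b / bg_b)`; `N` bases contribute 0. The per-motif threshold is
chosen so that one background window matches with probability 10⁻⁴,
computed by exact dynamic programming over the discretized per-position
score distributions (discretization 10⁻⁴ log₂-odds units, padded by half a
unit per position so float-scored hits are a subset of the counted tail).
Enrichment compares binary region hits in the target set against the
pooled target+background total with a one-sided hypergeometric test,
BH-corrected across motifs. The background set is user-supplied; no
GC-matched background is auto-generated — the synthetic generator controls
composition instead.

## Single-cell preprocessing

QC cascade, in order: (1) cells with <500 detected genes removed; (2)
genes detected in <10% of the remaining cells removed; (3) on the
gene-filtered matrix, cells with total counts outside [2000, 9000] or
mitochondrial count fraction >5% removed. "Counts per cell" is read as
total transcript counts (a `detected` mode applies the window to
detected-gene numbers instead; the source phrasing supports either).
Normalization is `ln(1 + count/cell_total × 10⁶)`.

Cell-cycle phase scores follow the binned-control construction: genes are
ranked by average expression into 25 equal-size bins and each phase gene
contributes 100 control genes drawn from its bin; the score is mean(set) −
mean(controls), seeded and deterministic. Mitochondrial fraction and the
two phase scores are regressed out per gene by ordinary least squares with
intercept; a rank-deficient design is an error that names the collinear
columns. Scores (not raw phase-gene expression) are used as covariates, as
that is what the scoring function exists for. Variable genes are those
with mean normalized expression in [0.5, 8] and variance-to-mean ratio in
[0.5, 5], bounds inclusive, sample variance with ddof = 1.

## Co-expression network

The biweight midcorrelation uses the standard tuning constant 9: with
`u = (x − med)/(9·MAD)` the weights are `(1 − u²)²·1(|u| < 1)`; a vector
with zero MAD falls back to Pearson-style mean-centering (a hybrid when
only one side falls back, exactly Pearson when both do); a constant vector
is an error. No outlier-proportion capping is applied. Signed adjacency is
`a_ij = ((1 + cor_ij)/2)^β` with unit diagonal. The topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with `k_i = Σ_{j≠i} a_ij`, `TOM_ii = 1`, symmetrized and clipped to [0, 1].

The scale-free criterion bins connectivities into 10 equal-occupancy
(quantile) bins, regresses log₁₀ frequency-density on log₁₀ mean
connectivity, and reports `−sign(slope)·R²`; `pick_soft_power` returns the
smallest candidate β reaching the target (default 0.8), or the maximizer
flagged `target_met=False`. Module detection clusters `1 − TOM` with
average linkage and a static cut (default height 0.99); clusters below the
minimum size (default 200 genes) are pooled into `unassigned`, and labels
M1, M2, … are ordered by decreasing size. The static cut plus
small-cluster merge is a deliberate simplification of the hybrid dynamic
tree cut, recorded in the partition metadata; recovery of planted module
structure is the contract it is tested against. Per-cluster networks use
the normalized (residual) expression of that cluster's cells, and module ×
candidate-gene intersection is tested hypergeometrically against the
retained-gene universe.

The module-recovery benchmark fixes β = 12 (the typical value for signed
networks of this kind) rather than running `pick_soft_power`: a planted
block-structured network is not scale-free by construction, so the
scale-free criterion is not a meaningful selector there, although on the
default benchmark it does reach the 0.8 target at moderate powers.

## Synthetic data: what it emulates

Every pipeline input is generated with planted truth recorded in a
manifest. Defaults are the package's study conditions and are not
per-experiment dials:

- **Genome**: 2 chromosomes, 5 Mb + 3 Mb — large enough for ≥500 disjoint
  regions, small enough for exhaustive oracles.
- **Regions**: 300 enhancers + 200 promoters; lengths log-normal (median
  ≈ 1.2 kb, clipped to 0.4–6 kb) so both sides of the 1 kb density
  eligibility cutoff are populated; non-overlapping with ≥100 bp gaps,
  placed by a stick-breaking construction that samples uniformly among
  valid configurations (and raises a capacity error when none exists).
  Each region links to 1–3 genes from a shared catalog (70% of region
  count), so some genes have multiple supporting regions.
- **SNCs**: per region, modern-only with probability 0.3 (the planted
  candidates), archaic-contaminated with probability 0.2 (≥1 archaic SNC,
  plus modern SNCs half the time so the depletion filter is exercised),
  else empty. Modern frequencies are 1.0 with probability 0.5, otherwise
  uniform on [0.90, 1.0). Background SNCs of both lineages fall outside
  all regions at 2×10⁻⁵ per bp.
- **Feature sets** (sweep-region/disease-locus analogues): 50 features of
  20–40 kb, a scaled-down analogue of selective-sweep scale; a fraction
  ρ is forced to overlap distinct random candidates, the rest placed
  uniformly. The length default also serves a statistical design purpose
  chosen a priori: with ~150 candidates and ~30 kb features on an 8 Mb
  genome the per-region null overlap probability is ≈0.2, giving the
  binary overlap statistic enough distinct values (null SD ≈ 5) that the
  empirical p-value grid is fine relative to its spacing — a requirement
  for the null p-value distribution to be near-uniform — while keeping
  ≥90% power at ρ = 0.5.
- **Sequences**: i.i.d. bases at 41% GC per region; a planted fraction
  receives one instance sampled column-wise from the PWM at a uniform
  position and strand. The example PWM is a 12-mer with 0.85 dominant-base
  probability per position — crisp enough that a sampled instance exceeds
  the 10⁻⁴ threshold ~90% of the time while background windows match at
  ~10⁻⁴.
- **Counts**: 120 cells × 1200 genes; log-rate = baseline + cluster-marker
  effect + module loading × per-cell latent factor + phase effect; counts
  are gamma-Poisson (NB dispersion 0.25) at softmax-normalized rates times
  a log-normal library size (median ≈ 4500, within the 2000–9000 QC
  window but with tails on both sides). Four modules of 250 genes with
  loadings U(0.8, 1.3) and baselines N(0.6, 0.8) — module membership is a
  property of expressed program genes, and these effect sizes make
  bicor-based recovery well-posed, which is the generator's contract; 13
  mitochondrial genes at ~3% of counts with per-cell jitter crossing the
  5% cutoff; 40 G1/S and 50 G2/M genes upshifted in cells assigned those
  phases; 3 cell clusters with 40 marker genes each.

Every generator is a pure function of its parameters and seed
(byte-identical reruns), and the manifest is verified against independent
recounts of the emitted files in the test suite.

**What the synthetic data does not emulate**: real base composition or
GC-heterogeneous backgrounds, linkage disequilibrium, genome masks and
gaps, Hi-C contact-distance decay (linkages are arbitrary), realistic
sweep-region length distributions, ambient RNA/doublets, or batch
structure. Passing tests therefore establish correctness of the
computations and calibration of the statistics under the stated generative
assumptions — not robustness to the artifacts of real catalogs, which
should be assessed on the real deposited datasets.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale sizes chosen as the
package's own validation conditions: 10 × 500-region datasets for exact
recovery; 500 null and 100 enriched replicates at 1000 permutations for
calibration and power; 20 × 1000-region instances for the ranking oracle;
full enumeration for the hypergeometric oracle up to N = 15; 50–100-gene
instances for the TOM oracle; a 10-seed grid of the 4 × 250-gene module
benchmark; and 100 seeds each for motif sensitivity and specificity. All
randomness flows through explicit integer seeds (NumPy `SeedSequence`
children), so every reported number is reproducible.

## Known limitations

- The hybrid dynamic tree cut and ontology-aware multiple-testing
  corrections are replaced by simpler, testable variants (static cut +
  merge; BH) and labelled as such in outputs.
- The permutation null ignores genome masks; on real assemblies this
  overstates the accessible placement space.
- Headline counts from the motivating real-data analysis (e.g. 212 linked
  genes) depend on externally deposited datasets and are not reproduced
  here; the pipeline reports their synthetic analogues instead.
- bicor's hybrid Pearson fallback means correlations involving highly
  zero-inflated genes are effectively Pearson; on very sparse data the
  robustness advantage of bicor is limited.
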