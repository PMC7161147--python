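"""Synthetic inputs with planted ground truth.

Every generator here is a pure function of its parameters and seed and
returns, alongside the data, the entries of a :class:`TruthManifest` that
record the planted structure (candidate regions, fixed-change genes,
overlap enrichment level, motif-bearing sequences, co-expression modules,
cell clusters). The defaults emulate, at desk scale, the statistical regime
of a developing-cortex regulatory catalog: a toy two-chromosome genome,
a few hundred enhancers/promoters of ~0.4-6 kb linked to a shared gene
catalog, lineage-specific single-nucleotide changes at fixed or >=90%
frequency, selective-sweep-scale feature regions of tens of kb, and a
negative-binomial single-cell count matrix with latent-factor modules,
cluster effects, cell-cycle phases and mitochondrial content.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .core import GenomicInterval, RegulatoryRegion, SNCRecord, merge_intervals

__all__ = [
    "GenomeSpec",
    "TruthManifest",
    "DEFAULT_GENOME",
    "simulate_regions",
    "simulate_sncs",
    "simulate_peaks",
    "simulate_feature_sets",
    "simulate_sequences_with_motif",
    "simulate_counts",
]

BASES = np.array(["A", "C", "G", "T"])


class CapacityError(RuntimeError):
    """The genome cannot hold the requested non-overlapping regions."""


@dataclass(frozen=True)
class GenomeSpec:
    """Toy genome: ordered (chromosome name, length in bp) pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([l for _, l in self.chromosomes], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())


#: Two chromosomes of 5 Mb and 3 Mb: large enough for >=500 disjoint
#: regions, small enough for exhaustive brute-force oracles.
DEFAULT_GENOME = GenomeSpec((("1", 5_000_000), ("2", 3_000_000)))


@dataclass
class TruthManifest:
    """Planted ground truth for one synthetic dataset."""

    rng_seed: int
    candidate_region_ids: set[str] = field(default_factory=set)
    fixed_enhancer_genes: set[str] = field(default_factory=set)
    fixed_promoter_genes: set[str] = field(default_factory=set)
    both_genes: set[str] = field(default_factory=set)
    candidate_genes: set[str] = field(default_factory=set)
    adult_pass_enhancers: set[str] = field(default_factory=set)
    planted_overlap_fraction: dict[str, float] = field(default_factory=dict)
    planted_motif: tuple[str, float] | None = None
    planted_motif_ids: set[str] = field(default_factory=set)
    module_assignment: dict[str, str] = field(default_factory=dict)
    cluster_assignment: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in (
            "candidate_region_ids",
            "fixed_enhancer_genes",
            "fixed_promoter_genes",
            "both_genes",
            "candidate_genes",
            "adult_pass_enhancers",
            "planted_motif_ids",
        ):
            d[key] = sorted(d[key])
        if d["planted_motif"] is not None:
            d["planted_motif"] = list(d["planted_motif"])
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        for key in (
            "candidate_region_ids",
            "fixed_enhancer_genes",
            "fixed_promoter_genes",
            "both_genes",
            "candidate_genes",
            "adult_pass_enhancers",
            "planted_motif_ids",
        ):
            d[key] = set(d.get(key, []))
        if d.get("planted_motif") is not None:
            d["planted_motif"] = tuple(d["planted_motif"])
        return cls(**d)


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_len: int,
    lengths: np.ndarray,
    min_gap: int,
) -> np.ndarray:
    """Uniform placement of disjoint intervals with pairwise gaps >= min_gap.

    Stick-breaking construction: the free slack is split by sorted uniforms,
    which draws uniformly from all valid configurations in one pass (no
    retry loop); raises :class:`CapacityError` when the slack is negative.
    """
    k = len(lengths)
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    slack = chrom_len - int(lengths.sum()) - min_gap * (k - 1)
    if slack < 0:
        raise CapacityError(
            f"cannot place {k} regions totalling {int(lengths.sum())} bp "
            f"with {min_gap} bp gaps on a {chrom_len} bp chromosome"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=k))
    shifted = np.concatenate([[0], np.cumsum(lengths[:-1] + min_gap)])
    return (offsets + shifted).astype(np.int64)


def simulate_regions(
    genome: GenomeSpec = DEFAULT_GENOME,
    n_enh: int = 300,
    n_prom: int = 200,
    length_log_mean: float = 7.1,
    length_log_sd: float = 0.45,
    length_min: int = 400,
    length_max: int = 6000,
    min_gap: int = 100,
    genes_per_region: tuple[int, int] = (1, 3),
    gene_catalog_size: int | None = None,
    rng_seed: int = 0,
) -> tuple[list[RegulatoryRegion], pd.DataFrame]:
    """Place non-overlapping enhancers/promoters and link them to genes.

    Region lengths are log-normal (default median ~1.2 kb, clipped to
    [400, 6000] bp so both sides of the 1 kb density-ranking eligibility
    cutoff are populated). Each region is linked to 1-3 genes drawn from a
    shared synthetic catalog, so some genes are supported by several
    regions. Returns the regions (with gene sets filled) and the linkage
    table (one row per region-gene pair).
    """
    rng = np.random.default_rng(rng_seed)
    n_total = n_enh + n_prom
    classes = np.array(["enhancer"] * n_enh + ["promoter"] * n_prom)
    lengths = np.clip(
        np.round(rng.lognormal(length_log_mean, length_log_sd, size=n_total)),
        length_min,
        length_max,
    ).astype(np.int64)
    # scatter regions over chromosomes in proportion to their lengths
    probs = genome.lengths / genome.total_length
    chrom_idx = rng.choice(len(probs), size=n_total, p=probs)

    order = np.arange(n_total)
    starts = np.empty(n_total, dtype=np.int64)
    for ci, (_, clen) in enumerate(genome.chromosomes):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        idx = order[mask]
        perm = rng.permutation(len(idx))  # random left-to-right order
        placed = _place_nonoverlapping(rng, clen, lengths[idx[perm]], min_gap)
        starts[idx[perm]] = placed

    if gene_catalog_size is None:
        gene_catalog_size = max(10, int(round(0.7 * n_total)))
    catalog = np.array([f"G{i:05d}" for i in range(gene_catalog_size)])

    regions: list[RegulatoryRegion] = []
    link_rows: list[tuple] = []
    counters = {"enhancer": 0, "promoter": 0}
    prefix = {"enhancer": "enh", "promoter": "prom"}
    for i in range(n_total):
        cls = classes[i]
        counters[cls] += 1
        rid = f"{prefix[cls]}_{counters[cls]:04d}"
        chrom = genome.names[chrom_idx[i]]
        iv = GenomicInterval(chrom, int(starts[i]), int(starts[i] + lengths[i]))
        n_genes = int(rng.integers(genes_per_region[0], genes_per_region[1] + 1))
        genes = rng.choice(catalog, size=n_genes, replace=False)
        regions.append(
            RegulatoryRegion(rid, iv, cls, source="fetal", genes=frozenset(genes.tolist()))
        )
        for g in sorted(genes.tolist()):
            link_rows.append((rid, chrom, iv.start, iv.end, cls, g))
    linkage = pd.DataFrame(
        link_rows, columns=["region_id", "chrom", "start", "end", "region_class", "gene_id"]
    )
    return regions, linkage


def _random_allele_pair(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    anc = rng.integers(0, 4, size=n)
    der = (anc + rng.integers(1, 4, size=n)) % 4
    return BASES[anc], BASES[der]


def simulate_sncs(
    regions: Sequence[RegulatoryRegion],
    genome: GenomeSpec = DEFAULT_GENOME,
    p_modern_only: float = 0.3,
    p_archaic: float = 0.2,
    p_fixed_given_modern: float = 0.5,
    p_modern_given_archaic: float = 0.5,
    modern_extra_rate: float = 1.0,
    background_rate: float = 2e-5,
    rng_seed: int = 0,
) -> tuple[list[SNCRecord], TruthManifest]:
    """Plant lineage-specific SNCs in regions and record the truth.

    Each region is independently assigned a status: *modern-only* (with
    probability ``p_modern_only``; these are the true candidates),
    *archaic-contaminated* (``p_archaic``; >=1 archaic SNC, and modern SNCs
    too with probability ``p_modern_given_archaic`` so the depletion filter
    is exercised), or *empty*. Modern SNC frequencies are 1.0 with
    probability ``p_fixed_given_modern`` and otherwise uniform on
    [0.90, 1.0). Background SNCs (both lineages) are scattered outside all
    regions at ``background_rate`` per bp. The manifest records the exact
    candidate-region set and the fixed-change gene sets implied by the
    planted frequencies.
    """
    if not 0 <= p_modern_only + p_archaic <= 1:
        raise ValueError("status probabilities must sum to <= 1")
    rng = np.random.default_rng(rng_seed)
    records: list[SNCRecord] = []
    manifest = TruthManifest(rng_seed=rng_seed)

    def add_modern(region: RegulatoryRegion, n: int) -> bool:
        """Plant n modern SNCs; returns True if any is fixed."""
        pos = rng.choice(region.length, size=min(n, region.length), replace=False)
        anc, der = _random_allele_pair(rng, len(pos))
        fixed_mask = rng.random(len(pos)) < p_fixed_given_modern
        freqs = np.where(fixed_mask, 1.0, rng.uniform(0.90, 1.0 - 1e-9, size=len(pos)))
        for p, a, d, f in zip(pos, anc, der, freqs):
            records.append(
                SNCRecord(region.interval.chrom, region.interval.start + int(p) + 1, a, d, "modern", float(f))
            )
        return bool(fixed_mask.any())

    def add_archaic(region: RegulatoryRegion, n: int) -> None:
        pos = rng.choice(region.length, size=min(n, region.length), replace=False)
        anc, der = _random_allele_pair(rng, len(pos))
        for p, a, d in zip(pos, anc, der):
            records.append(
                SNCRecord(region.interval.chrom, region.interval.start + int(p) + 1, a, d, "archaic", 1.0)
            )

    for region in regions:
        u = rng.random()
        if u < p_modern_only:
            n_m = 1 + rng.poisson(modern_extra_rate)
            any_fixed = add_modern(region, n_m)
            manifest.candidate_region_ids.add(region.region_id)
            manifest.candidate_genes.update(region.genes)
            if any_fixed:
                if region.region_class == "enhancer":
                    manifest.fixed_enhancer_genes.update(region.genes)
                else:
                    manifest.fixed_promoter_genes.update(region.genes)
        elif u < p_modern_only + p_archaic:
            add_archaic(region, 1 + rng.poisson(0.5))
            if rng.random() < p_modern_given_archaic:
                add_modern(region, 1 + rng.poisson(modern_extra_rate))
    manifest.both_genes = manifest.fixed_enhancer_genes & manifest.fixed_promoter_genes

    # background SNCs strictly outside every region
    merged = merge_intervals([r.interval for r in regions])
    n_bg = rng.poisson(background_rate * genome.total_length)
    if n_bg:
        probs = genome.lengths / genome.total_length
        chrom_idx = rng.choice(len(probs), size=n_bg, p=probs)
        anc, der = _random_allele_pair(rng, n_bg)
        lineage = np.where(rng.random(n_bg) < 0.5, "modern", "archaic")
        freqs = np.where(rng.random(n_bg) < 0.5, 1.0, rng.uniform(0.90, 1.0 - 1e-9, size=n_bg))
        for i in range(n_bg):
            chrom = genome.names[chrom_idx[i]]
            pos0 = int(rng.integers(0, genome.lengths[chrom_idx[i]]))
            runs = merged.get(chrom)
            if runs is not None and len(runs):
                j = np.searchsorted(runs[:, 0], pos0, side="right") - 1
                if j >= 0 and runs[j, 1] > pos0:
                    continue  # would corrupt planted truth
            records.append(
                SNCRecord(chrom, pos0 + 1, anc[i], der[i], str(lineage[i]), float(freqs[i]))
            )
    return records, manifest


def simulate_feature_sets(
    genome: GenomeSpec,
    candidates: Sequence[RegulatoryRegion],
    rho: float,
    n_features: int = 50,
    length_range: tuple[int, int] = (20_000, 40_000),
    rng_seed: int = 0,
) -> list[GenomicInterval]:
    """Feature regions (sweep-region / disease-locus analogues).

    ``round(rho * n_features)`` features are forced to overlap a randomly
    chosen candidate region (distinct candidates while they last); the rest
    are placed uniformly over the genome. Default lengths (20-40 kb) are a
    scaled-down analogue of selective-sweep scale.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_forced = int(round(rho * n_features))
    if n_forced > 0 and not candidates:
        raise ValueError("cannot force overlap with an empty candidate set")
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_features)
    chrom_len = dict(genome.chromosomes)

    features: list[GenomicInterval] = []
    if n_forced:
        replace = n_forced > len(candidates)
        picked = rng.choice(len(candidates), size=n_forced, replace=replace)
        for i, ci in enumerate(picked):
            c = candidates[int(ci)].interval
            l = int(lengths[i])
            lo = max(0, c.start - l + 1)
            hi = min(chrom_len[c.chrom] - l, c.end - 1)
            if hi < lo:  # feature longer than chromosome remnant; pin to start
                lo = hi = max(0, min(c.start, chrom_len[c.chrom] - l))
            s = int(rng.integers(lo, hi + 1))
            features.append(GenomicInterval(c.chrom, s, s + l))
    for i in range(n_forced, n_features):
        l = int(lengths[i])
        valid = np.maximum(genome.lengths - l + 1, 0)
        probs = valid / valid.sum()
        ci = int(rng.choice(len(probs), p=probs))
        s = int(rng.integers(0, valid[ci]))
        features.append(GenomicInterval(genome.names[ci], s, s + l))
    return features


def simulate_peaks(
    enhancers: Sequence[RegulatoryRegion],
    genome: GenomeSpec = DEFAULT_GENOME,
    p_contained: float = 0.6,
    p_peak_me3: float = 0.2,
    pad_range: tuple[int, int] = (50, 500),
    n_background_me3: int = 100,
    me3_length_range: tuple[int, int] = (500, 2000),
    rng_seed: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval], set[str]]:
    """Histone-mark peak sets (H3K27ac, H3K4me3) with containment truth.

    Each enhancer gets, with probability ``p_contained``, an H3K27ac peak
    that fully contains it (random padding on each side); with probability
    ``p_peak_me3`` that peak is overlapped by an H3K4me3 peak, which
    disqualifies it. Additional background H3K4me3 peaks are scattered
    uniformly. Returns (h3k27ac, h3k4me3, ids of enhancers expected to pass
    the containment-without-promoter-signal filter), the truth recomputed
    by an independent double loop over the emitted peak sets.
    """
    rng = np.random.default_rng(rng_seed)
    chrom_len = dict(genome.chromosomes)
    k27: list[GenomicInterval] = []
    me3: list[GenomicInterval] = []
    for e in enhancers:
        if rng.random() >= p_contained:
            continue
        iv = e.interval
        lpad = int(rng.integers(*pad_range))
        rpad = int(rng.integers(*pad_range))
        peak = GenomicInterval(
            iv.chrom, max(0, iv.start - lpad), min(chrom_len[iv.chrom], iv.end + rpad)
        )
        k27.append(peak)
        if rng.random() < p_peak_me3:
            l = int(rng.integers(*me3_length_range))
            s = int(rng.integers(max(0, peak.start - l + 1), peak.end - 1 + 1))
            me3.append(GenomicInterval(peak.chrom, s, min(chrom_len[peak.chrom], s + l)))
    for _ in range(n_background_me3):
        l = int(rng.integers(*me3_length_range))
        probs = np.maximum(genome.lengths - l + 1, 0)
        ci = int(rng.choice(len(probs), p=probs / probs.sum()))
        s = int(rng.integers(0, genome.lengths[ci] - l + 1))
        me3.append(GenomicInterval(genome.names[ci], s, s + l))

    from .core import contains, overlaps

    passing: set[str] = set()
    for e in enhancers:
        for p in k27:
            if contains(p, e.interval) and not any(overlaps(p, m) for m in me3):
                passing.add(e.region_id)
                break
    return k27, me3, passing


def simulate_sequences_with_motif(
    regions: Sequence[tuple[str, int]],
    pwm,
    fraction_planted: float,
    gc: float = 0.41,
    rng_seed: int = 0,
) -> tuple[dict[str, str], set[str]]:
    """I.i.d. background sequences with a motif instance planted in a fraction.

    ``regions`` is a sequence of (id, length) pairs. Each planted region
    receives one instance sampled column-wise from the PWM, inserted at a
    uniform position on a uniform strand. Returns the sequences and the set
    of planted ids.
    """
    from .enrichment.motifs import sample_instance, reverse_complement

    if not 0 <= fraction_planted <= 1:
        raise ValueError("fraction_planted must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    m = pwm.length
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ids = [rid for rid, _ in regions]
    lengths = {rid: int(l) for rid, l in regions}
    for rid, l in lengths.items():
        if l < m:
            raise ValueError(f"region {rid} shorter than motif ({l} < {m})")
    n_plant = int(round(fraction_planted * len(ids)))
    planted = set(rng.choice(ids, size=n_plant, replace=False).tolist()) if n_plant else set()

    seqs: dict[str, str] = {}
    for rid in ids:
        l = lengths[rid]
        seq = "".join(BASES[rng.choice(4, size=l, p=base_probs)])
        if rid in planted:
            inst = sample_instance(pwm, rng)
            if rng.random() < 0.5:
                inst = reverse_complement(inst)
            p = int(rng.integers(0, l - m + 1))
            seq = seq[:p] + inst + seq[p + m:]
        seqs[rid] = seq
    return seqs, planted


def simulate_counts(
    n_cells: int = 120,
    n_genes: int = 1200,
    n_clusters: int = 3,
    n_modules: int = 4,
    module_size: int = 250,
    libsize_log_mean: float = np.log(4500.0),
    libsize_log_sd: float = 0.35,
    nb_dispersion: float = 0.25,
    mito_n_genes: int = 13,
    mito_weight: float = 5.7,
    n_g1s: int = 40,
    n_g2m: int = 50,
    module_loading_range: tuple[float, float] = (0.8, 1.3),
    cluster_effect: float = 1.0,
    markers_per_cluster: int = 40,
    phase_effect: float = 1.2,
    rng_seed: int = 0,
) -> tuple[ad.AnnData, TruthManifest]:
    """Negative-binomial single-cell counts with planted module structure.

    Per-cell gene rates follow ``log-rate = baseline + cluster marker effect
    + module loading x per-cell latent factor + phase effect``; expected
    counts are the cell's library size times the softmax of the rates, and
    counts are gamma-Poisson (NB) with dispersion ``nb_dispersion``.
    Designated mitochondrial genes get a high baseline with per-cell
    jitter so the 5% QC cutoff is exercised; designated G1/S and G2/M gene
    sets are upshifted in cells assigned to the corresponding phase.

    Returns an AnnData (cells x genes, raw integer counts in ``X``; truth
    labels in ``obs``/``var``) and a manifest with the module and cluster
    assignments.
    """
    if n_modules * module_size > n_genes:
        raise ValueError("n_modules * module_size must not exceed n_genes")
    rng = np.random.default_rng(rng_seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])

    # designate special gene groups among the non-module tail
    perm = rng.permutation(n_genes)
    module_genes = perm[: n_modules * module_size]
    rest = perm[n_modules * module_size:]
    if len(rest) < mito_n_genes + n_g1s + n_g2m:
        raise ValueError("not enough non-module genes for mito and cell-cycle sets")
    mito_idx = rest[:mito_n_genes]
    g1s_idx = rest[mito_n_genes: mito_n_genes + n_g1s]
    g2m_idx = rest[mito_n_genes + n_g1s: mito_n_genes + n_g1s + n_g2m]
    genes = genes.copy()
    for j, gi in enumerate(mito_idx):
        genes[gi] = f"MT-{j + 1:02d}"

    module_of = np.full(n_genes, -1)
    for m in range(n_modules):
        module_of[module_genes[m * module_size: (m + 1) * module_size]] = m

    baseline = rng.normal(0.0, 1.2, size=n_genes)
    # co-expression programs are defined on expressed genes: module members
    # draw their baseline from the detectable range
    baseline[module_genes] = rng.normal(0.6, 0.8, size=len(module_genes))
    baseline[mito_idx] = np.log(mito_weight)

    clusters = rng.integers(0, n_clusters, size=n_cells)
    marker_sets = []
    nonmodule_pool = rest[mito_n_genes + n_g1s + n_g2m:]
    pool = nonmodule_pool if len(nonmodule_pool) >= markers_per_cluster else rest
    for _ in range(n_clusters):
        marker_sets.append(rng.choice(pool, size=min(markers_per_cluster, len(pool)), replace=False))

    phase = rng.choice(["G1S", "G2M", "G0"], size=n_cells, p=[0.2, 0.2, 0.6])
    loadings = rng.uniform(*module_loading_range, size=n_genes)
    factors = rng.normal(0.0, 1.0, size=(n_modules, n_cells))
    mito_jitter = rng.lognormal(0.0, 0.35, size=n_cells)
    libsize = rng.lognormal(libsize_log_mean, libsize_log_sd, size=n_cells)

    logw = np.tile(baseline[:, None], (1, n_cells))
    for m in range(n_modules):
        sel = module_of == m
        logw[sel, :] += loadings[sel, None] * factors[m][None, :]
    for k in range(n_clusters):
        cells_k = clusters == k
        logw[np.ix_(marker_sets[k], cells_k)] += cluster_effect
    logw[np.ix_(g1s_idx, phase == "G1S")] += phase_effect
    logw[np.ix_(g2m_idx, phase == "G2M")] += phase_effect
    logw[mito_idx, :] += np.log(mito_jitter)[None, :]

    w = np.exp(logw)
    mu = w / w.sum(axis=0, keepdims=True) * libsize[None, :]
    if nb_dispersion > 0:
        lam = rng.gamma(1.0 / nb_dispersion, nb_dispersion * mu)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "true_cluster": [f"C{c + 1}" for c in clusters],
            "phase": phase,
        },
        index=cell_ids,
    )
    var = pd.DataFrame(
        {
            "mito": np.isin(np.arange(n_genes), mito_idx),
            "g1s": np.isin(np.arange(n_genes), g1s_idx),
            "g2m": np.isin(np.arange(n_genes), g2m_idx),
            "true_module": [f"M{m + 1}" if m >= 0 else "none" for m in module_of],
        },
        index=genes,
    )
    adata = ad.AnnData(X=counts.T, obs=obs, var=var)

    manifest = TruthManifest(rng_seed=rng_seed)
    manifest.module_assignment = {
        genes[i]: f"M{module_of[i] + 1}" for i in range(n_genes) if module_of[i] >= 0
    }
    manifest.cluster_assignment = dict(zip(cell_ids, obs["true_cluster"]))
    return adata, manifest
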