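"""Selection of candidate regulatory regions and their genes.

The procedure: annotate each enhancer/promoter with the lineage-specific
single-nucleotide changes (SNCs) it contains; keep regions that harbor >=1
modern-human SNC and are depleted of (i.e. contain zero) archaic SNCs; for
an adult-enhancer set, additionally require complete containment in an
active-enhancer (H3K27ac) peak that is free of promoter (H3K4me3) signal;
finally resolve the linked gene list and classify genes by whether a linked
enhancer and/or promoter carries a *fixed* modern SNC.

"Fixed" means derived-allele frequency >= 1 - epsilon (default epsilon
1e-6); catalogs reporting an explicit fixed flag override the frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, RegulatoryRegion, SNCRecord, LINEAGES

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyClass",
    "GeneEvidence",
    "annotate_regions",
    "select_candidates",
    "adult_enhancer_filter",
    "resolve_gene_list",
    "classify_fixed_genes",
]


class FrequencyClass(str, Enum):
    """Derived-allele frequency class of a modern SNC."""

    FIXED = "fixed"
    NEARLY_FIXED = "nearly_fixed"

    @classmethod
    def of(cls, snc: SNCRecord, epsilon: float = 1e-6) -> "FrequencyClass":
        return cls.FIXED if snc.is_fixed(epsilon) else cls.NEARLY_FIXED


@dataclass
class RegionSupport:
    region_id: str
    region_class: str
    n_modern: int
    n_modern_fixed: int


@dataclass
class GeneEvidence:
    """Why a gene is on the candidate list."""

    gene_id: str
    enhancer_fixed: bool = False
    promoter_fixed: bool = False
    supporting_regions: list[RegionSupport] = field(default_factory=list)


def _sorted_positions(sncs: Iterable[SNCRecord]):
    """Per-(chrom, lineage) sorted 0-based positions, plus fixed flags for modern."""
    by_key: dict[tuple[str, str], list[tuple[int, bool]]] = {}
    for s in sncs:
        if s.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {s.lineage!r}")
        by_key.setdefault((s.chrom, s.lineage), []).append((s.pos - 1, s.is_fixed()))
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, vals in by_key.items():
        vals.sort()
        pos = np.array([p for p, _ in vals], dtype=np.int64)
        fixed = np.array([f for _, f in vals], dtype=bool)
        out[key] = (pos, fixed)
    return out


def annotate_regions(
    regions: Sequence[RegulatoryRegion],
    sncs: Sequence[SNCRecord],
    epsilon: float = 1e-6,
) -> list[RegulatoryRegion]:
    """Fill per-region SNC counts (n_modern, n_modern_fixed, n_archaic)."""
    for s in sncs:
        if s.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {s.lineage!r}")
    by_key: dict[tuple[str, str], list[tuple[int, float, bool | None]]] = {}
    for s in sncs:
        by_key.setdefault((s.chrom, s.lineage), []).append((s.pos - 1, s.frequency, s.fixed))
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, vals in by_key.items():
        vals.sort(key=lambda t: t[0])
        pos = np.array([p for p, _, _ in vals], dtype=np.int64)
        fixed = np.array(
            [(f if f is not None else q >= 1.0 - epsilon) for _, q, f in vals], dtype=bool
        )
        index[key] = (pos, fixed)

    annotated = []
    for r in regions:
        iv = r.interval
        n_m = n_mf = n_a = 0
        hit = index.get((iv.chrom, "modern"))
        if hit is not None:
            pos, fixed = hit
            lo, hi = np.searchsorted(pos, (iv.start, iv.end))
            n_m = int(hi - lo)
            n_mf = int(fixed[lo:hi].sum())
        hit = index.get((iv.chrom, "archaic"))
        if hit is not None:
            pos, _ = hit
            lo, hi = np.searchsorted(pos, (iv.start, iv.end))
            n_a = int(hi - lo)
        annotated.append(r.with_counts(n_m, n_mf, n_a))
    return annotated


def select_candidates(regions: Sequence[RegulatoryRegion]) -> list[RegulatoryRegion]:
    """Regions harboring >=1 modern SNC and depleted of archaic SNCs."""
    return [r for r in regions if r.n_modern >= 1 and r.n_archaic == 0]


def adult_enhancer_filter(
    enhancers: Sequence[RegulatoryRegion],
    h3k27ac_peaks: Sequence[GenomicInterval],
    h3k4me3_peaks: Sequence[GenomicInterval],
    mode: str = "peak",
) -> list[RegulatoryRegion]:
    """Keep enhancers fully contained in promoter-free active-enhancer signal.

    ``mode="peak"`` (default): an enhancer passes iff it is completely
    contained in >=1 H3K27ac peak that itself has zero overlap with any
    H3K4me3 peak. ``mode="enhancer"``: the H3K4me3 exclusion is applied to
    the enhancer interval instead of the peak.
    """
    if mode not in ("peak", "enhancer"):
        raise ValueError("mode must be 'peak' or 'enhancer'")
    from .core import merge_intervals, overlaps_merged

    me3 = merge_intervals(h3k4me3_peaks)

    def overlaps_me3(iv: GenomicInterval) -> bool:
        return bool(
            overlaps_merged(me3, iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
        )

    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in h3k27ac_peaks:
        if mode == "enhancer" or not overlaps_me3(p):
            peaks_by_chrom.setdefault(p.chrom, []).append(p)

    passing = []
    for e in enhancers:
        iv = e.interval
        if mode == "enhancer" and overlaps_me3(iv):
            continue
        for p in peaks_by_chrom.get(iv.chrom, ()):
            if p.start <= iv.start and iv.end <= p.end:
                passing.append(e)
                break
    return passing


def resolve_gene_list(
    candidates: Sequence[RegulatoryRegion],
    linkage: pd.DataFrame,
) -> tuple[set[str], dict[str, GeneEvidence]]:
    """Union of genes linked to candidate regions, with per-gene evidence.

    A candidate region missing from the linkage table is excluded with a
    warning (logged), not an error.
    """
    links: dict[str, set[str]] = {
        str(rid): set(grp["gene_id"].astype(str)) for rid, grp in linkage.groupby("region_id")
    }
    evidence: dict[str, GeneEvidence] = {}
    for r in candidates:
        genes = r.genes or links.get(r.region_id)
        if not genes:
            logger.warning("candidate region %s missing from linkage; excluded", r.region_id)
            continue
        for g in genes:
            ev = evidence.setdefault(g, GeneEvidence(gene_id=g))
            ev.supporting_regions.append(
                RegionSupport(r.region_id, r.region_class, r.n_modern, r.n_modern_fixed)
            )
            if r.n_modern_fixed >= 1:
                if r.region_class == "enhancer":
                    ev.enhancer_fixed = True
                else:
                    ev.promoter_fixed = True
    return set(evidence), evidence


def classify_fixed_genes(
    evidence: dict[str, GeneEvidence],
) -> tuple[set[str], set[str], set[str]]:
    """(enhancer_fixed, promoter_fixed, both) gene sets.

    Membership requires >=1 fixed modern SNC in a linked candidate region of
    the respective class; ``both`` is the intersection.
    """
    enh = {g for g, ev in evidence.items() if ev.enhancer_fixed}
    prom = {g for g, ev in evidence.items() if ev.promoter_fixed}
    return enh, prom, enh & prom


def gene_list_table(evidence: dict[str, GeneEvidence]) -> pd.DataFrame:
    """Flat per-gene summary (gene, n_regions, classes, fixed flags)."""
    rows = []
    for g in sorted(evidence):
        ev = evidence[g]
        classes = sorted({s.region_class for s in ev.supporting_regions})
        rows.append(
            (
                g,
                len(ev.supporting_regions),
                ",".join(classes),
                ev.enhancer_fixed,
                ev.promoter_fixed,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_regions", "classes", "enhancer_fixed", "promoter_fixed"]
    )
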