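"""Genomic interval primitives and overlap queries.

All internal coordinates are 0-based half-open (BED convention). Variant
catalogs report 1-based positions (VCF convention); :func:`point_to_interval`
performs the conversion on ingest. Chromosome names are compared as exact
strings after optional normalization of a leading ``chr`` prefix
(:func:`normalize_chrom`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "SNCRecord",
    "RegulatoryRegion",
    "IntervalIndex",
    "normalize_chrom",
    "point_to_interval",
    "overlaps",
    "contains",
    "count_hits",
    "merge_intervals",
]

LINEAGES = frozenset({"modern", "archaic"})


class InvalidCoordinateError(ValueError):
    """A coordinate violates the 1-based / half-open conventions."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise InvalidCoordinateError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise InvalidCoordinateError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SNCRecord:
    """A lineage-specific single-nucleotide change.

    ``pos`` is 1-based (catalog convention). ``lineage`` is ``"modern"`` for
    derived alleles on the modern-human branch (Neanderthal/Denisovan
    ancestral) and ``"archaic"`` for the converse. ``frequency`` is the
    derived-allele frequency in present-day humans, in (0, 1]; catalogs that
    only distinguish "fixed" from ">=90%" classes may set ``fixed=True``
    explicitly, which overrides the frequency-based classification.
    """

    chrom: str
    pos: int
    ancestral: str
    derived: str
    lineage: str
    frequency: float
    fixed: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidCoordinateError(f"pos is 1-based, got {self.pos}")
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles must differ")
        if self.lineage not in LINEAGES:
            raise ValueError(f"lineage must be one of {sorted(LINEAGES)}, got {self.lineage!r}")
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"frequency must be in (0, 1], got {self.frequency}")

    @property
    def interval(self) -> GenomicInterval:
        return point_to_interval(self.chrom, self.pos)

    def is_fixed(self, epsilon: float = 1e-6) -> bool:
        if self.fixed is not None:
            return self.fixed
        return self.frequency >= 1.0 - epsilon


@dataclass
class RegulatoryRegion:
    """A regulatory element (enhancer or promoter) and its variant annotation.

    ``genes`` stays empty until linkage resolution; the ``n_*`` counts are
    filled by annotation against an SNC catalog.
    """

    region_id: str
    interval: GenomicInterval
    region_class: str  # "enhancer" | "promoter"
    source: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)
    n_modern: int = 0
    n_modern_fixed: int = 0
    n_archaic: int = 0

    def __post_init__(self) -> None:
        if self.region_class not in ("enhancer", "promoter"):
            raise ValueError(f"region_class must be enhancer|promoter, got {self.region_class!r}")
        if min(self.n_modern, self.n_modern_fixed, self.n_archaic) < 0:
            raise ValueError("annotation counts must be >= 0")
        if self.n_modern_fixed > self.n_modern:
            raise ValueError("n_modern_fixed cannot exceed n_modern")

    @property
    def length(self) -> int:
        return len(self.interval)

    def with_counts(self, n_modern: int, n_modern_fixed: int, n_archaic: int) -> "RegulatoryRegion":
        return replace(
            self, n_modern=n_modern, n_modern_fixed=n_modern_fixed, n_archaic=n_archaic
        )


def normalize_chrom(name: str, strip_prefix: bool = True) -> str:
    """Normalize a chromosome name; by default drops a leading ``chr``."""
    name = name.strip()
    if strip_prefix and name.lower().startswith("chr"):
        name = name[3:]
    return name


def point_to_interval(chrom: str, pos_1based: int) -> GenomicInterval:
    """Convert a 1-based point position to a half-open 0-based interval."""
    if pos_1based < 1:
        raise InvalidCoordinateError(f"1-based position must be >= 1, got {pos_1based}")
    return GenomicInterval(chrom, pos_1based - 1, pos_1based)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies completely within ``outer``."""
    return outer.chrom == inner.chrom and outer.start <= inner.start and inner.end <= outer.end


def count_hits(region: GenomicInterval, points: Iterable[SNCRecord]) -> int:
    """Number of SNCs whose (converted) position falls inside ``region``."""
    n = 0
    for p in points:
        if overlaps(region, p.interval):
            n += 1
    return n


class IntervalIndex:
    """Overlap-query index over a set of intervals.

    Query results are guaranteed identical to a brute-force scan over the
    underlying set (property-tested). Backed by one interval tree per
    chromosome.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, len(self._items))
        self._items.append(iv)

    def __len__(self) -> int:
        return len(self._items)

    def query(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """All stored intervals overlapping ``iv``, in insertion order."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        idx = sorted(hit.data for hit in tree.overlap(iv.start, iv.end))
        return [self._items[i] for i in idx]

    def query_point(self, chrom: str, pos_1based: int) -> list[GenomicInterval]:
        return self.query(point_to_interval(chrom, pos_1based))

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlaps(iv.start, iv.end))


def merge_intervals(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge intervals into disjoint sorted runs per chromosome.

    Returns ``{chrom: array of shape (n, 2)}`` with columns (start, end).
    Useful for vectorized binary-overlap checks: because merged runs are
    disjoint and sorted, an interval [s, e) overlaps the set iff the run with
    the largest start < e (if any) ends after s.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        runs: list[list[int]] = []
        for s, e in ivs:
            if runs and s <= runs[-1][1]:
                runs[-1][1] = max(runs[-1][1], e)
            else:
                runs.append([s, e])
        merged[chrom] = np.asarray(runs, dtype=np.int64)
    return merged


def overlaps_merged(merged: dict[str, np.ndarray], chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorized binary overlap of query intervals against merged runs."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    runs = merged.get(chrom)
    if runs is None or len(runs) == 0:
        return np.zeros(starts.shape, dtype=bool)
    idx = np.searchsorted(runs[:, 0], ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = runs[idx[hit], 1] > starts[hit]
    return hit
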