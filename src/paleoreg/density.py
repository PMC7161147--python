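"""Mutation-density ranking of regulatory regions.

Density is modern-SNC hits per bp, computed only for regions of at least
``min_length`` bp (default 1000); the top ``fraction`` (default 5%) by
density is flagged *within each region class* (enhancers and promoters
ranked separately). Ties at the flagging boundary are broken
deterministically: longer region first, then lexicographic region id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import RegulatoryRegion

__all__ = ["DensityRecord", "mutation_density", "top_fraction", "density_table"]


@dataclass
class DensityRecord:
    region_id: str
    region_class: str
    length: int
    hits: int
    density: float
    rank: int | None = None
    top_flag: bool = False


def mutation_density(
    regions: Sequence[RegulatoryRegion],
    min_length: int = 1000,
    fixed_only: bool = False,
) -> list[DensityRecord]:
    """Hits-per-bp records for eligible (>= min_length bp) regions.

    ``fixed_only`` restricts the numerator to fixed modern SNCs; the default
    counts all modern SNCs (fixed + nearly fixed).
    """
    records = []
    for r in regions:
        if r.length < min_length:
            continue
        hits = r.n_modern_fixed if fixed_only else r.n_modern
        records.append(
            DensityRecord(r.region_id, r.region_class, r.length, hits, hits / r.length)
        )
    return records


def _sort_key(rec: DensityRecord):
    # highest density first; ties: longer first, then id ascending
    return (-rec.density, -rec.length, rec.region_id)


def top_fraction(
    records: Sequence[DensityRecord],
    fraction: float = 0.05,
    per_class: bool = True,
) -> list[DensityRecord]:
    """Flag the ceil(fraction * n) highest-density records per class.

    Returns new records with ``rank`` (1-based within class) and
    ``top_flag`` set, ordered by class then rank.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    groups: dict[str, list[DensityRecord]] = {}
    for rec in records:
        groups.setdefault(rec.region_class if per_class else "all", []).append(rec)
    out: list[DensityRecord] = []
    for cls in sorted(groups):
        recs = sorted(groups[cls], key=_sort_key)
        n_top = math.ceil(fraction * len(recs))
        for i, rec in enumerate(recs):
            out.append(
                DensityRecord(
                    rec.region_id, rec.region_class, rec.length, rec.hits, rec.density,
                    rank=i + 1, top_flag=i < n_top,
                )
            )
    return out


def density_table(records: Sequence[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.region_id, r.region_class, r.length, r.hits, r.density, r.rank, r.top_flag)
            for r in records
        ],
        columns=["region_id", "class", "length", "hits", "density", "rank", "top_flag"],
    )
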