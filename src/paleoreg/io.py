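"""Readers/writers for the plain-text formats the pipeline consumes.

BED files are 3+ column, tab-separated, 0-based half-open; columns 4-6 are
preserved as an opaque payload. SNC catalogs are headered TSV with 1-based
positions. Region-gene linkages are headered TSV with one row per
region-gene pair. Gene sets use GMT; sequences use FASTA via Biopython.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    GenomicInterval,
    InvalidCoordinateError,
    RegulatoryRegion,
    SNCRecord,
    normalize_chrom,
)

SNC_COLUMNS = ["chrom", "pos", "ancestral", "derived", "lineage", "frequency"]
LINKAGE_COLUMNS = ["region_id", "chrom", "start", "end", "region_class", "gene_id"]


def read_bed(path: str | Path, strip_chr: bool = True) -> pd.DataFrame:
    """Read a BED file into a DataFrame (chrom, start, end, payload columns).

    Zero-length or inverted intervals are rejected; '#' comment and 'track'
    lines are skipped.
    """
    rows: list[list[str]] = []
    ncols = 3
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line has <3 columns: {line!r}")
            ncols = max(ncols, len(parts))
            rows.append(parts)
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, ncols + 1)]
    df = pd.DataFrame([r + [""] * (ncols - len(r)) for r in rows], columns=cols)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df["chrom"] = df["chrom"].map(lambda c: normalize_chrom(c, strip_chr))
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if not bad.empty:
        r = bad.iloc[0]
        raise InvalidCoordinateError(
            f"zero-length or invalid interval {r['chrom']}:{r['start']}-{r['end']}"
        )
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [GenomicInterval(c, int(s), int(e)) for c, s, e in zip(df["chrom"], df["start"], df["end"])]


def intervals_to_bed(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in intervals], columns=["chrom", "start", "end"]
    )


def read_snc_tsv(path: str | Path, strip_chr: bool = True) -> list[SNCRecord]:
    """Read an SNC catalog (header required; '#' comments allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in SNC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNC TSV missing columns: {missing}")
    has_fixed = "fixed" in df.columns
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SNCRecord(
                chrom=normalize_chrom(str(row.chrom), strip_chr),
                pos=int(row.pos),
                ancestral=str(row.ancestral),
                derived=str(row.derived),
                lineage=str(row.lineage),
                frequency=float(row.frequency),
                fixed=bool(row.fixed) if has_fixed and pd.notna(row.fixed) else None,
            )
        )
    return records


def write_snc_tsv(records: Sequence[SNCRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.pos, r.ancestral, r.derived, r.lineage, r.frequency) for r in records],
        columns=SNC_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_linkage_tsv(path: str | Path, strip_chr: bool = True) -> pd.DataFrame:
    """Region-gene linkage table: one row per (region, gene) pair."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "region_id": str, "gene_id": str})
    missing = [c for c in LINKAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"linkage TSV missing columns: {missing}")
    df["chrom"] = df["chrom"].map(lambda c: normalize_chrom(c, strip_chr))
    return df


def write_linkage_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=LINKAGE_COLUMNS)


def regions_from_linkage(linkage: pd.DataFrame, source: str = "") -> list[RegulatoryRegion]:
    """Build RegulatoryRegion objects (with gene sets) from a linkage table."""
    regions = []
    for rid, grp in linkage.groupby("region_id", sort=True):
        first = grp.iloc[0]
        regions.append(
            RegulatoryRegion(
                region_id=str(rid),
                interval=GenomicInterval(str(first["chrom"]), int(first["start"]), int(first["end"])),
                region_class=str(first["region_class"]),
                source=source,
                genes=frozenset(grp["gene_id"].astype(str)),
            )
        )
    return regions


def regions_to_bed(regions: Sequence[RegulatoryRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.interval.chrom, r.interval.start, r.interval.end, r.region_id, r.region_class) for r in regions],
        columns=["chrom", "start", "end", "col4", "col5"],
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA keyed by record id (region_id convention)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """GMT gene sets: term, description, genes...; returns term -> gene set."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")
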