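"""Permutation-based region-set overlap enrichment.

The observed statistic is the number of query regions overlapping at least
one feature region. The null is built by repeatedly re-placing the query
regions (length-preserving, uniform over all valid placements in the
genome); the empirical p-value is (b + 1) / (n_perm + 1) where b counts
permutations at least as extreme as the observation, so it can never be 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..core import GenomicInterval, merge_intervals
from ..simulate import GenomeSpec

__all__ = ["PermutationResult", "randomize_regions", "permutation_overlap_test"]


@dataclass
class PermutationResult:
    observed: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    p_value: float
    z_score: float
    alternative: str


def _placement_probs(genome: GenomeSpec, length: int) -> np.ndarray:
    valid = np.maximum(genome.lengths - length + 1, 0)
    total = valid.sum()
    if total == 0:
        raise ValueError(f"region of length {length} does not fit on any chromosome")
    return valid / total


def randomize_regions(
    regions: Sequence[GenomicInterval],
    genome: GenomeSpec,
    rng: np.random.Generator | int = 0,
    keep_chrom: bool = False,
) -> list[GenomicInterval]:
    """Length-preserving uniform re-placement of a region set.

    Each region keeps its length; its start is uniform over the valid start
    positions and its chromosome is drawn with probability proportional to
    the number of valid placements on it (equivalently, uniform over all
    valid placements genome-wide). With ``keep_chrom`` the original
    chromosome is retained.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    chrom_len = dict(genome.chromosomes)
    out = []
    for r in regions:
        l = len(r)
        if keep_chrom:
            cl = chrom_len[r.chrom]
            if l > cl:
                raise ValueError(f"region longer than its chromosome ({l} > {cl})")
            s = int(rng.integers(0, cl - l + 1))
            out.append(GenomicInterval(r.chrom, s, s + l))
        else:
            probs = _placement_probs(genome, l)
            ci = int(rng.choice(len(probs), p=probs))
            s = int(rng.integers(0, genome.lengths[ci] - l + 1))
            out.append(GenomicInterval(genome.names[ci], s, s + l))
    return out


def _count_overlaps_batch(
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    lengths: np.ndarray,
    merged_arrays: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Per-row count of intervals overlapping >=1 merged feature run.

    ``chrom_idx``/``starts`` have shape (n_draws, n_regions); merged_arrays
    holds (run_starts, run_ends) per chromosome index.
    """
    hits = np.zeros(chrom_idx.shape, dtype=bool)
    ends = starts + lengths[None, :]
    for ci, (rs, re) in enumerate(merged_arrays):
        if rs.size == 0:
            continue
        mask = chrom_idx == ci
        if not mask.any():
            continue
        idx = np.searchsorted(rs, ends[mask], side="left") - 1
        ok = idx >= 0
        ok[ok] = re[idx[ok]] > starts[mask][ok]
        hits[mask] = ok
    return hits.sum(axis=1)


def permutation_overlap_test(
    query: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    genome: GenomeSpec,
    n_perm: int = 10_000,
    rng_seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Test over-representation of query regions in a feature set.

    Statistic: number of query regions overlapping >=1 feature. Null:
    ``n_perm`` length-preserving uniform randomizations of the query set
    (vectorized). ``alternative`` is "greater" (enrichment) or "less".
    """
    if len(query) == 0:
        raise ValueError("empty query set: overlap statistic undefined")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = np.random.default_rng(rng_seed)

    merged = merge_intervals(features)
    name_to_idx = {name: i for i, name in enumerate(genome.names)}
    merged_arrays = []
    for name in genome.names:
        runs = merged.get(name)
        if runs is None or len(runs) == 0:
            merged_arrays.append((np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)))
        else:
            merged_arrays.append((runs[:, 0].copy(), runs[:, 1].copy()))

    lengths = np.array([len(r) for r in query], dtype=np.int64)
    obs_chrom = np.array([[name_to_idx[r.chrom] for r in query]])
    obs_start = np.array([[r.start for r in query]], dtype=np.int64)
    observed = int(_count_overlaps_batch(obs_chrom, obs_start, lengths, merged_arrays)[0])

    # vectorized randomization: per region, chromosome CDF over valid placements
    n_q = len(query)
    valid = np.maximum(genome.lengths[None, :] - lengths[:, None] + 1, 0)  # (n_q, n_chrom)
    if np.any(valid.sum(axis=1) == 0):
        bad = lengths[valid.sum(axis=1) == 0].max()
        raise ValueError(f"region of length {bad} does not fit on any chromosome")
    cdf = np.cumsum(valid, axis=1) / valid.sum(axis=1, keepdims=True)
    u = rng.random((n_perm, n_q))
    chrom_idx = np.empty((n_perm, n_q), dtype=np.int64)
    for j in range(n_q):
        chrom_idx[:, j] = np.searchsorted(cdf[j], u[:, j], side="right")
    span = valid[np.arange(n_q)[None, :], chrom_idx]  # valid placements per draw
    starts = (rng.random((n_perm, n_q)) * span).astype(np.int64)
    null = _count_overlaps_batch(chrom_idx, starts, lengths, merged_arrays)

    if alternative == "greater":
        b = int(np.sum(null >= observed))
    else:
        b = int(np.sum(null <= observed))
    p = (b + 1) / (n_perm + 1)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else float("nan")
    return PermutationResult(observed, n_perm, mean, sd, p, z, alternative)
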