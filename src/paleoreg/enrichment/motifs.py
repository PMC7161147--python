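"""Known-motif (PWM) scanning and enrichment.

A PWM stores per-position base probabilities; scanning scores every window
on both strands with the log2-odds score sum(log2(p_base / bg_base)) and
reports windows at or above a threshold. The default threshold is chosen
per motif so that a single background window matches with probability
``1e-4`` (computed exactly by dynamic programming over the discretized
per-position score distribution). Enrichment of a target sequence set
against a background set is a one-sided hypergeometric test on binary
region hits, BH-corrected across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genesets import bh_adjust

__all__ = [
    "PWM",
    "MotifResult",
    "read_jaspar",
    "scan_pwm",
    "motif_enrichment",
    "threshold_from_pvalue",
    "sample_instance",
    "reverse_complement",
    "make_example_pwm",
]

_BASE_ORDER = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """Position weight matrix over A/C/G/T.

    ``matrix`` has shape (length, 4) with rows summing to 1 (within 1e-6);
    ``background`` is the base composition used for log-odds;
    ``score_threshold`` (log2-odds units) may be None, in which case
    scanners derive it from ``site_pvalue``.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = None
    score_threshold: float | None = None
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if np.any(np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("PWM columns must each sum to 1 (within 1e-6)")
        self.background = (
            UNIFORM_BG.copy() if self.background is None else np.asarray(self.background, dtype=float)
        )
        if self.score_threshold is not None and self.score_threshold > self.max_score + 1e-9:
            raise ValueError("score_threshold exceeds the maximum achievable score")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 5) log2-odds; column 4 (N) contributes 0."""
        p = (self.matrix + self.pseudocount) / (1.0 + 4 * self.pseudocount)
        lo = np.log2(p / self.background[None, :])
        return np.hstack([lo, np.zeros((self.length, 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.score_threshold,
            self.pseudocount,
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sample_instance(pwm: PWM, rng: np.random.Generator) -> str:
    """One motif instance sampled column-wise from the PWM probabilities."""
    return "".join(
        _BASE_ORDER[rng.choice(4, p=pwm.matrix[i] / pwm.matrix[i].sum())]
        for i in range(pwm.length)
    )


def read_jaspar(path: str | Path, **kwargs) -> list[PWM]:
    """Parse JASPAR-style plain-text PWMs (counts or probabilities)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([list(m.counts[b]) for b in _BASE_ORDER], dtype=float).T
            rowsum = counts.sum(axis=1, keepdims=True)
            if np.any(rowsum <= 0):
                raise ValueError(f"motif {m.matrix_id or m.name}: empty PWM column")
            name = m.matrix_id or m.name
            out.append(PWM(str(name), counts / rowsum, **kwargs))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            counts = np.round(p.matrix * scale).astype(int)
            for bi, base in enumerate(_BASE_ORDER):
                nums = " ".join(f"{c:6d}" for c in counts[:, bi])
                fh.write(f"{base}  [{nums} ]\n")


def threshold_from_pvalue(pwm: PWM, site_pvalue: float = 1e-4, precision: float = 1e-4) -> float:
    """Smallest score with P(window score >= t | background) <= site_pvalue.

    Exact (up to score discretization at ``precision`` log2-odds units)
    dynamic programming over the per-position score distributions under the
    background base composition.
    """
    if not 0 < site_pvalue < 1:
        raise ValueError("site_pvalue must be in (0, 1)")
    scale = 1.0 / precision
    lo = pwm.log_odds[:, :4]
    iscores = np.round(lo * scale).astype(np.int64)
    # iterative convolution; track the reachable sub-range to stay O(L * width)
    cur_min = cur_max = 0
    cur = np.array([1.0])
    for i in range(pwm.length):
        row = iscores[i]
        new_min = cur_min + int(row.min())
        new_max = cur_max + int(row.max())
        new = np.zeros(new_max - new_min + 1)
        for b in range(4):
            shift = int(row[b]) + cur_min - new_min
            new[shift: shift + len(cur)] += pwm.background[b] * cur
        cur, cur_min, cur_max = new, new_min, new_max
    tail = np.cumsum(cur[::-1])[::-1]
    # smallest integer score whose tail probability <= site_pvalue; capped at
    # the maximum achievable score (threshold must remain attainable)
    above = np.nonzero(tail <= site_pvalue)[0]
    t_int = cur_min + int(above[0]) if len(above) else cur_max
    # per-position rounding can shift a true window score by up to
    # length * precision / 2; pad so that float scores >= threshold are a
    # subset of the integer scores the tail counted
    return min(t_int / scale + pwm.length * precision / 2.0, pwm.max_score)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as e:
        raise ValueError(f"invalid base {e.args[0]!r} in sequence") from None


def _window_scores(codes: np.ndarray, lodds5: np.ndarray) -> np.ndarray:
    """Scores of all windows; codes is 1-D or 2-D (batch, seq_len)."""
    L = lodds5.shape[0]
    n = codes.shape[-1] - L + 1
    if n <= 0:
        return np.zeros(codes.shape[:-1] + (0,))
    scores = np.zeros(codes.shape[:-1] + (n,))
    for j in range(L):
        scores += lodds5[j][codes[..., j: j + n]]
    return scores


def scan_pwm(sequence: str, pwm: PWM, threshold: float | None = None) -> list[tuple[int, str, float]]:
    """All windows (both strands) scoring >= threshold.

    Returns (position, strand, score) tuples; positions are 0-based window
    starts on the forward sequence. ``N`` bases contribute 0 to the score.
    A sequence shorter than the motif yields an empty result.
    """
    if threshold is None:
        threshold = pwm.score_threshold
        if threshold is None:
            threshold = threshold_from_pvalue(pwm)
    codes = _encode(sequence.upper())
    hits = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _window_scores(codes, mat.log_odds)
        for pos in np.nonzero(scores >= threshold)[0]:
            hits.append((int(pos), strand, float(scores[pos])))
    hits.sort()
    return hits


def _hit_mask(seqs: Sequence[str], pwm: PWM, threshold: float) -> np.ndarray:
    """Binary >=1-hit flag per sequence, batching equal-length sequences."""
    fwd = pwm.log_odds
    rev = pwm.reverse_complement().log_odds
    mask = np.zeros(len(seqs), dtype=bool)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for l, idx in by_len.items():
        if l < pwm.length:
            continue
        codes = np.stack([_encode(seqs[i].upper()) for i in idx])
        hit = (_window_scores(codes, fwd) >= threshold).any(axis=1)
        hit |= (_window_scores(codes, rev) >= threshold).any(axis=1)
        mask[idx] = hit
    return mask


@dataclass
class MotifResult:
    motif_id: str
    targets_with_hit: int
    n_targets: int
    background_with_hit: int
    n_background: int
    p_value: float
    q_value: float = float("nan")
    threshold: float = float("nan")


def motif_enrichment(
    targets: Mapping[str, str],
    background: Mapping[str, str],
    pwms: Sequence[PWM],
    site_pvalue: float = 1e-4,
) -> list[MotifResult]:
    """Hypergeometric enrichment of motif-bearing regions in the target set.

    Per motif, each region scores a binary hit (>=1 occurrence on either
    strand at the motif's threshold); the target hit count is tested
    against the pooled target+background hit total (one-sided, upper tail),
    and q-values are BH across motifs.
    """
    if not targets or not background:
        raise ValueError("target and background sets must both be non-empty")
    t_seqs = list(targets.values())
    b_seqs = list(background.values())
    n_t, n_b = len(t_seqs), len(b_seqs)
    results = []
    for pwm in pwms:
        thr = pwm.score_threshold
        if thr is None:
            thr = threshold_from_pvalue(pwm, site_pvalue)
        if all(len(s) < pwm.length for s in t_seqs):
            warnings.warn(f"motif {pwm.motif_id} longer than every target region")
            results.append(MotifResult(pwm.motif_id, 0, n_t, 0, n_b, 1.0, threshold=thr))
            continue
        k_t = int(_hit_mask(t_seqs, pwm, thr).sum())
        k_b = int(_hit_mask(b_seqs, pwm, thr).sum())
        N, K = n_t + n_b, k_t + k_b
        p = float(stats.hypergeom.sf(k_t - 1, N, K, n_t))
        results.append(MotifResult(pwm.motif_id, k_t, n_t, k_b, n_b, p, threshold=thr))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    return results


def make_example_pwm(
    motif_id: str = "SYN_TF1",
    consensus: str = "TGACGTCATCGA",
    dominant: float = 0.85,
) -> PWM:
    """A crisp synthetic PWM: the consensus base gets ``dominant`` probability
    at each position, the rest split evenly."""
    mat = np.full((len(consensus), 4), (1 - dominant) / 3)
    for i, b in enumerate(consensus):
        mat[i, _CODE[b]] = dominant
    return PWM(motif_id, mat)
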