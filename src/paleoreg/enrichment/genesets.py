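"""Hypergeometric gene-set over-representation with BH correction.

For a query of ``n`` genes drawn from a universe of ``N`` and a term of
``K`` genes, the upper-tail hypergeometric p-value for an observed overlap
``k`` is ``P(X >= k)`` with ``X ~ Hypergeom(N, K, n)``. Multiple terms are
corrected with Benjamini-Hochberg (the correction column is labelled
``bh``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetResult", "hypergeom_pvalue", "hypergeom_gene_test", "bh_adjust"]


@dataclass
class GeneSetResult:
    term_id: str
    universe_size: int
    term_size: int
    query_size: int
    overlap: int
    p_value: float
    adj_p: float
    correction: str = "bh"


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric configuration N={N} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = list(pvalues)
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeom_gene_test(
    query: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[GeneSetResult]:
    """Per-term upper-tail hypergeometric tests with BH adjustment.

    ``query`` and every term are intersected with the universe; the query
    must be a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    q = set(query)
    if not q <= uni:
        raise ValueError(f"query genes outside universe: {sorted(q - uni)[:5]} ...")
    N, n = len(uni), len(q)
    rows = []
    for term_id in terms:
        t = set(terms[term_id]) & uni
        k = len(t & q)
        rows.append((term_id, len(t), k, hypergeom_pvalue(N, len(t), n, k)))
    adj = bh_adjust([r[3] for r in rows])
    return [
        GeneSetResult(term_id, N, K, n, k, p, a)
        for (term_id, K, k, p), a in zip(rows, adj)
    ]


def gene_test_table(results: list[GeneSetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.universe_size, r.term_size, r.query_size, r.overlap, r.p_value, r.adj_p, r.correction)
            for r in results
        ],
        columns=["term_id", "N", "K", "n", "k", "p_value", "adj_p", "correction"],
    )
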