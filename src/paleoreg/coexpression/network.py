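"""Weighted co-expression network construction and module detection.

The network follows the signed weighted construction: a robust biweight
midcorrelation (bicor) between genes, rescaled to [0, 1] and raised to a
soft power beta chosen by the scale-free topology criterion, then
transformed to a topological overlap matrix (TOM). Modules are found by
average-linkage hierarchical clustering of the 1 - TOM dissimilarity with a
static cut; clusters below the minimum size (default 200 genes in the
full-scale analysis) are pooled into an "unassigned" label. The static cut
plus small-cluster merge is a deliberate simplification of the hybrid
dynamic tree cut; the partition records it in its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ..enrichment.genesets import GeneSetResult, hypergeom_gene_test

__all__ = [
    "NetworkParams",
    "ModulePartition",
    "bicor",
    "bicor_matrix",
    "signed_adjacency",
    "pick_soft_power",
    "topological_overlap",
    "detect_modules",
    "intersect_modules",
]

UNASSIGNED = "unassigned"


class UndefinedCorrelationError(ValueError):
    """A vector is constant (or fully down-weighted): correlation undefined."""


@dataclass
class NetworkParams:
    beta: int
    r2: float
    min_module_size: int = 200
    correlation: str = "bicor"
    r2_target: float = 0.8
    target_met: bool = True


@dataclass
class ModulePartition:
    """Gene -> module label map; small clusters carry the unassigned label."""

    labels: dict[str, str]
    min_module_size: int
    cut_height: float
    method: str = "average-linkage static cut + small-cluster merge"

    @property
    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_sizes if m != UNASSIGNED]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="module")


def _bicor_transform(X: np.ndarray) -> np.ndarray:
    """Row-wise robust standardization used by bicor.

    For each row, deviations from the median are weighted by
    w = (1 - u^2)^2 * 1(|u| < 1) with u = (x - med) / (9 * MAD); rows with
    zero MAD fall back to the Pearson transform (mean-centering). Rows are
    then scaled to unit norm, so correlations are plain dot products.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        u = dev / (9.0 * mad)
        w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
        xt = np.where(np.isfinite(w), dev * w, 0.0)
    if fallback.any():
        xt[fallback] = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xt, axis=1)
    zero = norms == 0
    if zero.any():
        raise UndefinedCorrelationError(
            f"{int(zero.sum())} constant (or fully down-weighted) rows; "
            "correlation undefined"
        )
    return xt / norms[:, None]


def bicor(x: Sequence[float], y: Sequence[float]) -> float:
    """Biweight midcorrelation of two vectors (tuning constant 9 x MAD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("bicor requires two equal-length vectors of length >= 3")
    t = _bicor_transform(np.vstack([x, y]))
    return float(np.clip(t[0] @ t[1], -1.0, 1.0))


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """All pairwise bicor values of the rows of a genes x cells matrix."""
    t = _bicor_transform(X)
    c = np.clip(t @ t.T, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def signed_adjacency(cor: np.ndarray, beta: int) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.power((1.0 + np.asarray(cor, dtype=float)) / 2.0, beta)
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a weighted network.

    Connectivities k_i = sum_{j != i} a_ij are binned into ``n_bins``
    equal-occupancy bins; the log10 frequency density per bin is regressed
    on the log10 mean connectivity, and the fit is -sign(slope) * R^2 (a
    scale-free network has a negative slope, hence a positive index).
    Returns NaN for degenerate (all-equal) connectivities.
    """
    k = adjacency.sum(axis=1) - np.diag(adjacency)
    k = k[k > 0]
    if len(k) < n_bins or np.allclose(k, k[0]):
        return float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return float("nan")
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        width = edges[b + 1] - edges[b]
        if not sel.any() or width <= 0:
            continue
        density = sel.sum() / (len(k) * width)
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(density))
    if len(xs) < 3:
        return float("nan")
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - yhat) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_power(
    cor: np.ndarray,
    candidate_betas: Iterable[int] = range(1, 21),
    r2_target: float = 0.8,
    min_module_size: int = 200,
) -> NetworkParams:
    """Smallest beta whose signed scale-free fit reaches ``r2_target``.

    If no candidate reaches the target, the beta maximizing the fit is
    returned with ``target_met=False``.
    """
    betas = list(candidate_betas)
    if not betas:
        raise ValueError("candidate_betas must be non-empty")
    fits = []
    for beta in betas:
        a = signed_adjacency(cor, beta)
        fits.append(scale_free_fit(a))
    for beta, fit in zip(betas, fits):
        if not np.isnan(fit) and fit >= r2_target:
            return NetworkParams(beta, float(fit), min_module_size, "bicor", r2_target, True)
    arr = np.array([-np.inf if np.isnan(f) else f for f in fits])
    best = int(np.argmax(arr))
    return NetworkParams(
        betas[best], float(fits[best]), min_module_size, "bicor", r2_target, False
    )


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal.

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, where the shared-neighbor sum excludes u in {i, j} and
    k_i = sum_{j != i} a_ij; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be a symmetric square matrix")
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    s = a @ a  # includes u = i and u = j terms: a_ii*a_ij + a_ij*a_jj = 2 a_ij
    numer = s - 2.0 * a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    gene_names: Sequence[str],
    min_module_size: int = 200,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Cluster 1 - TOM by average linkage and label modules by size.

    A static cut at ``cut_height`` defines clusters; clusters smaller than
    ``min_module_size`` are pooled into the unassigned label. Module labels
    are M1, M2, ... ordered by decreasing size (ties by first gene id), so
    the partition is deterministic.
    """
    gene_names = list(gene_names)
    n = len(gene_names)
    if n != tom.shape[0]:
        raise ValueError("gene_names length must match the TOM dimension")
    if n < min_module_size:
        return ModulePartition(
            {g: UNASSIGNED for g in gene_names}, min_module_size, cut_height
        )
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    keep = [
        (len(idx), gene_names[min(idx)], idx)
        for idx in clusters.values()
        if len(idx) >= min_module_size
    ]
    keep.sort(key=lambda t: (-t[0], t[1]))
    labels = {g: UNASSIGNED for g in gene_names}
    for m, (_, _, idx) in enumerate(keep, start=1):
        for i in idx:
            labels[gene_names[i]] = f"M{m}"
    return ModulePartition(labels, min_module_size, cut_height)


def intersect_modules(
    partition: ModulePartition,
    candidate_genes: Iterable[str],
    include_unassigned: bool = False,
) -> tuple[dict[str, set[str]], list[GeneSetResult]]:
    """Candidate-gene membership per module, with hypergeometric enrichment.

    The universe is every gene in the partition; candidates outside the
    universe are ignored. Returns (module -> member candidates, per-module
    enrichment results).
    """
    universe = set(partition.labels)
    query = set(candidate_genes) & universe
    terms: dict[str, set[str]] = {}
    for g, m in partition.labels.items():
        if m == UNASSIGNED and not include_unassigned:
            continue
        terms.setdefault(m, set()).add(g)
    members = {m: terms[m] & query for m in terms}
    results = hypergeom_gene_test(query, terms, universe) if terms else []
    return members, results
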