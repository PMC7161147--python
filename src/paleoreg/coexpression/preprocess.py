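"""Single-cell preprocessing: QC filters, normalization, covariate control.

The QC thresholds follow the analysis this pipeline reproduces: cells need
>=500 detected genes; genes must be detected in >=10% of cells; cells must
have total counts in [2000, 9000] and a mitochondrial count fraction of at
most 5%. Normalization is LogNormalize with a 1e6 scale factor:
``ln(1 + count / cell_total * 1e6)``. Cell-cycle phase scores follow the
binned-control module-score construction (25 average-expression bins, 100
control genes per set gene), and unwanted covariates are removed per gene
by ordinary least squares.

Matrices are genes x cells throughout; the AnnData entry point
(:func:`qc_filter`) uses the cells-as-observations convention and carries a
boolean ``mito`` column in ``.var``.
"""

from __future__ import annotations

import numpy as np
import anndata as ad

__all__ = [
    "qc_filter",
    "log_normalize",
    "gene_set_score",
    "regress_out",
    "variable_genes",
]


class EmptyMatrixError(ValueError):
    """All cells (or genes) were removed by filtering."""


def qc_filter(
    adata: ad.AnnData,
    min_genes_per_cell: int = 500,
    min_cell_fraction: float = 0.10,
    min_counts: int = 2000,
    max_counts: int = 9000,
    max_mito_fraction: float = 0.05,
    count_mode: str = "total",
) -> ad.AnnData:
    """Apply the QC cascade and return the filtered copy.

    Order of application: (1) drop cells with fewer than
    ``min_genes_per_cell`` detected genes; (2) drop genes detected in fewer
    than ``min_cell_fraction`` of the remaining cells; (3) drop cells whose
    total counts fall outside [min_counts, max_counts] or whose
    mitochondrial fraction exceeds ``max_mito_fraction`` (both computed on
    the gene-filtered matrix). ``count_mode="detected"`` applies the count
    window to detected-gene numbers instead of totals.
    """
    if count_mode not in ("total", "detected"):
        raise ValueError("count_mode must be 'total' or 'detected'")
    X = np.asarray(adata.X)
    detected = (X > 0).sum(axis=1)
    keep_cells = detected >= min_genes_per_cell
    adata = adata[keep_cells].copy()
    if adata.n_obs == 0:
        raise EmptyMatrixError("no cells pass the detected-genes filter")

    X = np.asarray(adata.X)
    gene_frac = (X > 0).mean(axis=0)
    adata = adata[:, gene_frac >= min_cell_fraction].copy()
    if adata.n_vars == 0:
        raise EmptyMatrixError("no genes pass the detection-fraction filter")

    X = np.asarray(adata.X)
    totals = X.sum(axis=1)
    if count_mode == "total":
        counts_stat = totals
    else:
        counts_stat = (X > 0).sum(axis=1)
    keep = (counts_stat >= min_counts) & (counts_stat <= max_counts)
    if "mito" in adata.var:
        mito = np.asarray(adata.var["mito"], dtype=bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, X[:, mito].sum(axis=1) / totals, 0.0)
        keep &= mito_frac <= max_mito_fraction
        adata.obs["mito_fraction"] = mito_frac
    adata.obs["total_counts"] = totals
    adata.obs["genes_detected"] = (X > 0).sum(axis=1)
    adata = adata[keep].copy()
    if adata.n_obs == 0:
        raise EmptyMatrixError("no cells pass the count/mito filters")
    return adata


def log_normalize(counts: np.ndarray, scale: float = 1_000_000.0) -> np.ndarray:
    """LogNormalize a genes x cells count matrix.

    value = ln(1 + count / cell_total * scale); invariant to per-cell
    depth (doubling a cell's counts leaves its normalized values unchanged).
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cell with zero total counts cannot be normalized")
    return np.log1p(counts / totals[None, :] * scale)


def gene_set_score(
    norm: np.ndarray,
    gene_names: np.ndarray,
    gene_set: set[str] | list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    rng_seed: int = 0,
) -> np.ndarray:
    """Per-cell expression score of a gene set against binned controls.

    score(cell) = mean expression of the set genes - mean expression of
    control genes, where each set gene contributes ``n_ctrl`` controls drawn
    (with replacement) from its average-expression bin. ``norm`` is genes x
    cells; returns one score per cell.
    """
    gene_names = np.asarray(gene_names)
    set_idx = np.nonzero(np.isin(gene_names, list(gene_set)))[0]
    if len(set_idx) == 0:
        raise ValueError("gene set is empty after intersecting with the matrix")
    rng = np.random.default_rng(rng_seed)
    avg = norm.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1
    )
    ctrl_idx = []
    for gi in set_idx:
        pool = np.nonzero(bin_of == bin_of[gi])[0]
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)
    return norm[set_idx].mean(axis=0) - norm[ctrl_idx].mean(axis=0)


def regress_out(norm: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Per-gene OLS residuals after regressing on per-cell covariates.

    ``norm`` is genes x cells; ``covariates`` is cells x k (or a single
    vector). An intercept is always included, so residuals are centered.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != norm.shape[1]:
        cov = cov.T
    if cov.shape[0] != norm.shape[1]:
        raise ValueError("covariate rows must align with cells")
    design = np.hstack([np.ones((cov.shape[0], 1)), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            trial = np.hstack([kept, design[:, j: j + 1]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(j - 1)
            else:
                kept = trial
        raise ValueError(f"rank-deficient design: collinear covariate columns {bad}")
    coef, *_ = np.linalg.lstsq(design, norm.T, rcond=None)
    return norm - (design @ coef).T


def variable_genes(
    norm: np.ndarray,
    mean_range: tuple[float, float] = (0.5, 8.0),
    vmr_range: tuple[float, float] = (0.5, 5.0),
) -> np.ndarray:
    """Boolean mask of highly-variable genes (bounds inclusive).

    A gene qualifies if its mean normalized expression lies in
    ``mean_range`` and its variance-to-mean ratio in ``vmr_range``.
    """
    if norm.size == 0:
        raise ValueError("empty matrix")
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vmr = np.where(mean > 0, var / mean, 0.0)
    return (
        (mean >= mean_range[0])
        & (mean <= mean_range[1])
        & (vmr >= vmr_range[0])
        & (vmr <= vmr_range[1])
    )
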