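"""Glue for the co-expression stage: preprocessing then per-cluster networks."""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np

from .network import (
    ModulePartition,
    NetworkParams,
    bicor_matrix,
    detect_modules,
    pick_soft_power,
    signed_adjacency,
    topological_overlap,
)
from .preprocess import gene_set_score, log_normalize, qc_filter, regress_out

__all__ = ["preprocess", "build_network", "NetworkOutput"]


@dataclass
class NetworkOutput:
    partition: ModulePartition
    params: NetworkParams


def preprocess(
    adata: ad.AnnData,
    g1s_genes: set[str] | None = None,
    g2m_genes: set[str] | None = None,
    rng_seed: int = 0,
    **qc_kwargs,
) -> ad.AnnData:
    """QC-filter, LogNormalize, score cell-cycle phases, regress covariates.

    Adds a ``lognorm`` layer (LogNormalize, scale 1e6) and a ``residual``
    layer with mitochondrial fraction and cell-cycle scores regressed out
    per gene. Phase gene sets default to the ``g1s``/``g2m`` flags in
    ``.var`` when present.
    """
    adata = qc_filter(adata, **qc_kwargs)
    norm = log_normalize(np.asarray(adata.X).T)  # genes x cells
    adata.layers["lognorm"] = norm.T

    gene_names = np.asarray(adata.var_names)
    covs = []
    if "mito_fraction" in adata.obs:
        covs.append(np.asarray(adata.obs["mito_fraction"], dtype=float))
    if g1s_genes is None and "g1s" in adata.var:
        g1s_genes = set(gene_names[np.asarray(adata.var["g1s"], dtype=bool)])
    if g2m_genes is None and "g2m" in adata.var:
        g2m_genes = set(gene_names[np.asarray(adata.var["g2m"], dtype=bool)])
    for i, gs in enumerate((g1s_genes, g2m_genes)):
        if gs:
            score = gene_set_score(norm, gene_names, gs, rng_seed=rng_seed + i)
            adata.obs["g1s_score" if i == 0 else "g2m_score"] = score
            covs.append(score)
    if covs:
        resid = regress_out(norm, np.column_stack(covs))
        adata.layers["residual"] = resid.T
    else:
        adata.layers["residual"] = norm.T
    return adata


def build_network(
    norm: np.ndarray,
    gene_names,
    beta: int | None = None,
    candidate_betas=range(1, 21),
    r2_target: float = 0.8,
    min_module_size: int = 200,
    cut_height: float = 0.99,
) -> NetworkOutput:
    """bicor -> signed adjacency -> TOM -> module detection on genes x cells."""
    cor = bicor_matrix(norm)
    if beta is None:
        params = pick_soft_power(cor, candidate_betas, r2_target, min_module_size)
    else:
        from .network import scale_free_fit

        a = signed_adjacency(cor, beta)
        params = NetworkParams(beta, scale_free_fit(a), min_module_size, "bicor", r2_target)
    adj = signed_adjacency(cor, params.beta)
    tom = topological_overlap(adj)
    partition = detect_modules(tom, list(gene_names), min_module_size, cut_height)
    return NetworkOutput(partition, params)
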