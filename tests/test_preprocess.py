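"""Single-cell QC thresholds, normalization, scoring, covariate regression."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from paleoreg.coexpression import (
    gene_set_score,
    log_normalize,
    qc_filter,
    regress_out,
    variable_genes,
)
from paleoreg.coexpression.preprocess import EmptyMatrixError


def make_adata(X, mito=None):
    n_cells, n_genes = X.shape
    var = pd.DataFrame(index=[f"g{i}" for i in range(n_genes)])
    if mito is not None:
        var["mito"] = mito
    return ad.AnnData(
        X=np.asarray(X), obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]), var=var
    )


class TestQcFilter:
    def test_detected_gene_threshold_boundary(self):
        # 600 genes; cell0 detects 499, cell1 detects 500
        X = np.zeros((2, 600), dtype=int)
        X[0, :499] = 10
        X[1, :500] = 10
        out = qc_filter(make_adata(X), min_counts=0, max_counts=10**9, min_cell_fraction=0)
        assert list(out.obs_names) == ["c1"]

    def test_total_count_window_boundaries(self):
        X = np.zeros((4, 600), dtype=int)
        for i, total in enumerate((1999, 2000, 9000, 9001)):
            X[i, :550] = total // 550
            X[i, 0] += total - (total // 550) * 550
        out = qc_filter(make_adata(X), min_cell_fraction=0)
        assert list(out.obs_names) == ["c1", "c2"]

    def test_gene_detection_fraction_boundary(self):
        # 100 cells; gene0 in 9 cells, gene1 in 10 cells
        X = np.zeros((100, 600), dtype=int)
        X[:, 2:] = 5  # keep every cell above the detected-genes floor
        X[:9, 0] = 1
        X[:10, 1] = 1
        out = qc_filter(make_adata(X), min_counts=0, max_counts=10**9)
        assert "g0" not in out.var_names and "g1" in out.var_names

    def test_mito_fraction_boundary(self):
        X = np.zeros((2, 600), dtype=int)
        X[:, :600] = 5  # 3000 counts per cell
        mito = np.zeros(600, dtype=bool)
        mito[0] = True
        X[0, 0] = 155  # 3150 total, 155/3150 ~ 4.92%
        X[1, 0] = 170  # 3165 total, 170/3165 ~ 5.37%
        out = qc_filter(make_adata(X, mito=mito), min_cell_fraction=0)
        assert list(out.obs_names) == ["c0"]

    def test_all_cells_removed_raises(self):
        X = np.ones((3, 50), dtype=int)
        with pytest.raises(EmptyMatrixError):
            qc_filter(make_adata(X))

    def test_order_invariance(self, counts_dataset):
        adata, _ = counts_dataset
        out = qc_filter(adata)
        rng = np.random.default_rng(0)
        perm_c = rng.permutation(adata.n_obs)
        perm_g = rng.permutation(adata.n_vars)
        out2 = qc_filter(adata[perm_c][:, perm_g].copy())
        assert set(out.obs_names) == set(out2.obs_names)
        assert set(out.var_names) == set(out2.var_names)

    def test_detected_count_mode(self):
        X = np.zeros((2, 3000), dtype=int)
        X[0, :1999] = 5
        X[1, :2000] = 5
        out = qc_filter(make_adata(X), min_cell_fraction=0, count_mode="detected")
        assert list(out.obs_names) == ["c1"]


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self):
        X = np.array([[0.0, 5.0], [10.0, 5.0]])
        norm = log_normalize(X)
        assert norm[0, 0] == 0.0

    def test_single_count_single_total(self):
        norm = log_normalize(np.array([[1.0], [0.0]]))
        assert norm[0, 0] == pytest.approx(np.log1p(1e6), rel=1e-12)
        assert norm[0, 0] == pytest.approx(13.8155, abs=1e-4)

    def test_depth_invariance(self, rng):
        X = rng.integers(0, 50, size=(30, 8)).astype(float) + 1
        doubled = X.copy()
        doubled[:, 3] *= 2
        assert np.allclose(log_normalize(X)[:, 3], log_normalize(doubled)[:, 3])

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            log_normalize(np.zeros((5, 2)))

    def test_values_finite_nonnegative(self, rng):
        X = rng.integers(0, 100, size=(40, 12)).astype(float)
        X[:, 0] += 1
        norm = log_normalize(X + (X.sum(axis=0) == 0))
        assert np.isfinite(norm).all() and (norm >= 0).all()


class TestGeneSetScore:
    def test_null_scores_centered_at_zero(self, rng):
        norm = rng.normal(1.0, 0.3, size=(300, 50))
        genes = np.array([f"g{i}" for i in range(300)])
        score = gene_set_score(norm, genes, {f"g{i}" for i in range(0, 300, 10)}, rng_seed=0)
        assert abs(score.mean()) < 0.05

    def test_deterministic_given_seed(self, rng):
        norm = rng.normal(1.0, 0.3, size=(200, 40))
        genes = np.array([f"g{i}" for i in range(200)])
        s1 = gene_set_score(norm, genes, {"g1", "g5", "g9"}, rng_seed=3)
        s2 = gene_set_score(norm, genes, {"g1", "g5", "g9"}, rng_seed=3)
        assert np.array_equal(s1, s2)

    def test_planted_phase_effect_detected(self, counts_dataset):
        adata, _ = counts_dataset
        X = np.asarray(adata.X).T.astype(float)
        norm = log_normalize(X + (X.sum(axis=0) == 0))
        genes = np.asarray(adata.var_names)
        g1s = set(genes[np.asarray(adata.var["g1s"], dtype=bool)])
        score = gene_set_score(norm, genes, g1s, rng_seed=1)
        phase = np.asarray(adata.obs["phase"])
        assert score[phase == "G1S"].mean() > score[phase != "G1S"].mean() + 0.1

    def test_empty_intersection_rejected(self, rng):
        norm = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            gene_set_score(norm, np.array([f"g{i}" for i in range(10)]), {"absent"})


class TestRegressOut:
    def test_orthogonal_covariate_leaves_centered_values(self):
        cells = 40
        cov = np.tile([1.0, -1.0], cells // 2)
        gene = np.arange(cells, dtype=float)
        gene -= cov * (gene @ cov) / (cov @ cov)  # orthogonalize by construction
        resid = regress_out(gene[None, :], cov)
        assert np.allclose(resid, gene - gene.mean(), atol=1e-10)

    def test_exactly_linear_gene_has_zero_residuals(self, rng):
        cov = rng.normal(size=30)
        gene = 2.5 * cov + 1.0
        resid = regress_out(gene[None, :], cov)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        norm = rng.normal(size=(25, 60))
        covs = rng.normal(size=(60, 3))
        resid = regress_out(norm, covs)
        assert np.max(np.abs(resid @ covs)) < 1e-8
        assert np.max(np.abs(resid.sum(axis=1))) < 1e-8  # intercept included

    def test_collinear_design_named_in_error(self, rng):
        cov = rng.normal(size=20)
        covs = np.column_stack([cov, 2 * cov])
        with pytest.raises(ValueError, match="collinear"):
            regress_out(rng.normal(size=(5, 20)), covs)


class TestVariableGenes:
    def test_mean_and_vmr_boundaries(self, rng):
        n = 400

        def gene_with(mean, vmr):
            # two-point construction with exact sample mean and variance
            sd = np.sqrt(vmr * mean)
            x = np.repeat([1.0, -1.0], n // 2)
            return (x - x.mean()) / x.std(ddof=1) * sd + mean

        eps = 1e-3  # clear of float round-off, tight against the cutoffs
        rows = {
            # {0,1} and {6,10} patterns: the boundary means are exact floats
            "mean_exactly_low_bound": np.tile([0.0, 1.0], n // 2),
            "mean_exactly_high_bound": np.tile([6.0, 10.0], n // 2),
            "mean_below": gene_with(0.5 - eps, 1.0),
            "mean_above": gene_with(8.0 + eps, 1.0),
            "vmr_below": gene_with(2.0, 0.5 - eps),
            "vmr_just_inside_low": gene_with(2.0, 0.5 + eps),
            "vmr_just_inside_high": gene_with(2.0, 5.0 - eps),
            "vmr_above": gene_with(2.0, 5.0 + eps),
            "constant": np.full(n, 3.0),
        }
        norm = np.vstack(list(rows.values()))
        mask = variable_genes(norm)
        got = {name: bool(m) for name, m in zip(rows, mask)}
        assert got == {
            "mean_exactly_low_bound": True,   # mean 0.5, vmr ~0.501
            "mean_exactly_high_bound": True,  # mean 8.0, vmr ~0.501
            "mean_below": False,
            "mean_above": False,
            "vmr_below": False,
            "vmr_just_inside_low": True,
            "vmr_just_inside_high": True,
            "vmr_above": False,
            "constant": False,
        }

    def test_matches_bruteforce_recount(self, rng):
        norm = rng.gamma(2.0, 1.0, size=(200, 80))
        mask = variable_genes(norm)
        for i in range(200):
            mean = norm[i].mean()
            vmr = norm[i].var(ddof=1) / mean
            expect = 0.5 <= mean <= 8 and 0.5 <= vmr <= 5
            assert mask[i] == expect
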