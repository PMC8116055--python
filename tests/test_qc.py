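"""QC thresholds, log-normalization formula, variable genes and PCA."""

import numpy as np
import pytest
import scipy.sparse as sp

from atrace.datamodel import CountsBundle
from atrace.qc import (NormalizedMatrix, QCParams, lognormalize, qc_filter,
                       run_pca, select_hvg)


def bundle_from_dense(genes, gene_ids=None, tag_rows=0):
    genes = np.asarray(genes)
    g, n = genes.shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(g)]
    return CountsBundle(sp.csr_matrix(genes), sp.csr_matrix((tag_rows, n)),
                        gene_ids, [f"t{i}" for i in range(tag_rows)],
                        [f"c{i}" for i in range(n)])


def cell_with_detected(n_detected, n_genes=6000, mito_count=0):
    col = np.zeros(n_genes, dtype=int)
    col[:n_detected] = 1
    col[-1] = mito_count  # last gene is mitochondrial in these fixtures
    return col


class TestQcFilter:
    def make(self, detected_list, mito_pcts):
        n_genes = 6000
        cols = []
        for d, mp in zip(detected_list, mito_pcts):
            col = np.zeros(n_genes, dtype=int)
            col[:d] = 1
            if mp > 0:
                # mito gene gets enough counts for the requested percent
                total_other = d
                mito = int(round(mp / (100 - mp) * total_other))
                col[-1] = mito
            cols.append(col)
        genes = np.stack(cols, axis=1)
        ids = [f"g{i:04d}" for i in range(n_genes - 1)] + ["mt-nd1"]
        return bundle_from_dense(genes, gene_ids=ids)

    def test_exactly_250_detected_removed(self):
        b = self.make([250], [0])
        kept, report = qc_filter(b)
        assert kept.n_cells == 0
        assert report["fail_reason"].iloc[0] == "too_few_genes"

    def test_251_genes_kept(self):
        kept, _ = qc_filter(self.make([251], [0]))
        assert kept.n_cells == 1

    def test_three_strict_thresholds_together(self):
        """Detected {100, 251, 4999, 5000, 300} with mito {0,0,0,0,20}%:
        only the 251- and 4999-gene cells survive."""
        b = self.make([100, 251, 4999, 5000, 300], [0, 0, 0, 0, 20])
        kept, report = qc_filter(b)
        assert kept.n_cells == 2
        assert list(report["pass"]) == [False, True, True, False, False]
        assert report["fail_reason"].iloc[4] == "high_mito"

    def test_idempotent(self):
        b = self.make([100, 300, 700], [0, 0, 0])
        once, _ = qc_filter(b)
        twice, _ = qc_filter(once)
        assert twice.cell_ids == once.cell_ids

    def test_no_survivors_warns_not_raises(self):
        with pytest.warns(UserWarning, match="no cells"):
            kept, _ = qc_filter(self.make([10, 20], [0, 0]))
        assert kept.n_cells == 0


class TestLognormalize:
    def test_zero_count_stays_zero(self):
        b = bundle_from_dense([[0, 2], [3, 0]])
        norm = lognormalize(b)
        assert norm.log_expr[0, 0] == 0
        assert norm.log_expr[1, 1] == 0

    def test_single_gene_formula_by_hand(self):
        b = bundle_from_dense([[7]])
        norm = lognormalize(b)
        assert norm.log_expr[0, 0] == pytest.approx(np.log(1 + 10000))

    def test_depth_invariance(self):
        b1 = bundle_from_dense([[1], [3]])
        b2 = bundle_from_dense([[2], [6]])
        n1, n2 = lognormalize(b1), lognormalize(b2)
        np.testing.assert_allclose(n1.log_expr.toarray(), n2.log_expr.toarray())

    def test_monotone_in_counts_at_fixed_total(self):
        b = bundle_from_dense([[1, 2], [9, 8]])
        norm = lognormalize(b).log_expr.toarray()
        assert norm[0, 1] > norm[0, 0]
        assert norm[1, 1] < norm[1, 0]

    def test_zero_total_cell_warns(self):
        with pytest.warns(UserWarning, match="zero total"):
            norm = lognormalize(bundle_from_dense([[0, 1]]))
        assert norm.log_expr[0, 0] == 0


class TestSelectHvg:
    def test_identical_genes_tie_break_lexicographic(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(2, 30)
        genes = np.stack([col] * 6)  # identical distribution and values
        b = bundle_from_dense(genes, gene_ids=["gd", "ga", "gc", "gb", "gf", "ge"])
        assert select_hvg(b, 3) == ["ga", "gb", "gc"]

    def test_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(1)
        genes = rng.poisson(2, (200, 200))
        spiky = np.zeros(200, dtype=int)
        spiky[::10] = 20  # mean 2 like its bin mates, ~10x their variance
        genes[7] = spiky
        b = bundle_from_dense(genes)
        assert select_hvg(b, 5)[0] == "g007"

    def test_requesting_all_genes_returns_identity_set(self):
        rng = np.random.default_rng(2)
        b = bundle_from_dense(rng.poisson(2, (10, 30)))
        assert sorted(select_hvg(b, 10)) == sorted(b.gene_ids)


class TestRunPca:
    def make_norm(self, x):
        b = bundle_from_dense(np.asarray(x))
        return b, lognormalize(b)

    def test_collinear_points_pc1_explains_all(self):
        # three cells on the line y=x in 2-gene log space: rank-1 covariance
        expr = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        norm = NormalizedMatrix(
            log_expr=sp.csr_matrix(expr), gene_ids=["g0", "g1"],
            cell_ids=["c0", "c1", "c2"],
            detected_genes=np.array([2, 2, 2]), mito_pct=np.zeros(3))
        norm = run_pca(norm, ["g0", "g1"], n_pcs=2)
        assert norm.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_cells_have_identical_scores(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3, (10, 6))
        counts[:, 3] = counts[:, 0]
        b = bundle_from_dense(counts)
        norm = run_pca(lognormalize(b), b.gene_ids, n_pcs=3)
        np.testing.assert_allclose(norm.pca_scores[0], norm.pca_scores[3],
                                   atol=1e-10)

    def test_scaled_rows_standardized_and_clipped(self):
        rng = np.random.default_rng(4)
        b = bundle_from_dense(rng.poisson(3, (8, 50)))
        norm = run_pca(lognormalize(b), b.gene_ids, n_pcs=4)
        assert np.abs(norm.scaled_expr.mean(axis=1)).max() < 0.3  # post-clip
        assert np.abs(norm.scaled_expr).max() <= 10

    def test_reconstruction_error_decreases_with_n_pcs(self):
        rng = np.random.default_rng(5)
        b = bundle_from_dense(rng.poisson(3, (12, 40)))
        errs = []
        for k in (1, 3, 6):
            norm = run_pca(lognormalize(b), b.gene_ids, n_pcs=k)
            recon = norm.pca_loadings @ norm.pca_scores.T
            errs.append(np.linalg.norm(norm.scaled_expr
                                       - norm.scaled_expr.mean(axis=1,
                                                               keepdims=True)
                                       - recon))
        assert errs[0] > errs[1] > errs[2]

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(6)
        b = bundle_from_dense(rng.poisson(3, (10, 30)))
        n1 = run_pca(lognormalize(b), b.gene_ids, n_pcs=4)
        n2 = run_pca(lognormalize(b), b.gene_ids, n_pcs=4)
        np.testing.assert_array_equal(n1.pca_scores, n2.pca_scores)
        for k in range(4):
            j = np.argmax(np.abs(n1.pca_loadings[:, k]))
            assert n1.pca_loadings[j, k] > 0

    def test_excessive_n_pcs_rejected(self):
        b = bundle_from_dense(np.ones((4, 3), dtype=int))
        with pytest.raises(ValueError, match="n_pcs"):
            run_pca(lognormalize(b), b.gene_ids, n_pcs=4)


class TestQCParams:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            QCParams(min_genes=100, max_genes=50)
        with pytest.raises(ValueError):
            QCParams(max_mito_pct=0)
        with pytest.raises(ValueError):
            QCParams(n_hvg=10, n_pcs=20)
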