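"""Set-level model components: centering, correlation eigenstructure, the
mixed-model fit and its symmetries, BH adjustment, and screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmgsa import (
    DegenerateDataError,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ModelSpec,
    SampleMetadata,
    ValidationError,
    bh_fdr_adjust,
    center_by_group,
    fit_gene_set_model,
    gene_correlation_eigen,
    screen_gene_sets,
)
from oracles import bh_stepup_bruteforce


class TestCenterByGroup:
    def test_mean_subtraction(self):
        values = np.array([[0.0, 2.0, 1.0, 3.0]])
        group = np.array(["control", "control", "case", "case"])
        out = center_by_group(values, group)
        np.testing.assert_allclose(out, [[-1.0, 1.0, -1.0, 1.0]])

    def test_constant_gene_gives_zero_row(self):
        out = center_by_group(np.full((1, 4), 5.0), np.array(["a", "a", "b", "b"]))
        np.testing.assert_allclose(out, 0.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(3, 8))
        group = np.array(["a"] * 4 + ["b"] * 4)
        perm = rng.permutation(8)
        out1 = center_by_group(values, group)[:, perm]
        out2 = center_by_group(values[:, perm], group[perm])
        np.testing.assert_allclose(out1, out2)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            center_by_group(np.zeros((1, 3)), np.array(["a", "a", "b"]))


class TestGeneCorrelationEigen:
    def test_uncorrelated_genes_unit_eigenvalues(self):
        resid = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        basis = gene_correlation_eigen(resid, K_max=2)
        np.testing.assert_allclose(basis.eigenvalues, [1.0, 1.0], atol=1e-12)

    def test_perfectly_correlated_rank_one(self):
        resid = np.vstack([[1.0, -1.0, 2.0, -2.0], [2.0, -2.0, 4.0, -4.0]])
        basis = gene_correlation_eigen(resid, K_max=2)
        # rank 1: a single eigenpair survives
        assert basis.K == 1
        np.testing.assert_allclose(basis.eigenvalues, [2.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(basis.loadings[:, 0]), 1 / np.sqrt(2), atol=1e-12)

    def test_equicorrelation_closed_form(self):
        # rows h0 + h_i with mutually orthogonal +-1 vectors give an exact
        # 3x3 correlation matrix with all off-diagonals 0.5, whose spectrum
        # is {2, 0.5, 0.5} (roots of (1-l)^3 - 0.75(1-l) + 0.25)
        h0 = np.array([1, 1, 1, 1, -1, -1, -1, -1], float)
        h1 = np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
        h2 = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
        h3 = h1 * h2
        resid = np.vstack([h0 + h1, h0 + h2, h0 + h3])
        C = np.corrcoef(resid)
        np.testing.assert_allclose(C - np.eye(3), 0.5 * (1 - np.eye(3)), atol=1e-12)
        basis = gene_correlation_eigen(resid, K_max=3)
        np.testing.assert_allclose(basis.eigenvalues, [2.0, 0.5, 0.5], atol=1e-10)
        # independent oracle: direct eigensolve of the printed matrix
        oracle = np.sort(np.linalg.eigvalsh(np.full((3, 3), 0.5) + 0.5 * np.eye(3)))[::-1]
        np.testing.assert_allclose(basis.eigenvalues, oracle, atol=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(5)
        resid = rng.normal(size=(4, 30))
        basis = gene_correlation_eigen(resid, K_max=4)
        C = np.corrcoef(resid)
        rec = basis.loadings @ np.diag(basis.eigenvalues) @ basis.loadings.T
        np.testing.assert_allclose(rec, C, atol=1e-8)

    def test_zero_variance_gene_named(self):
        resid = np.vstack([np.zeros(4), [1.0, -1.0, 2.0, -2.0]])
        with pytest.raises(DegenerateDataError, match="0"):
            gene_correlation_eigen(resid, K_max=2)

    def test_trace_bound(self):
        rng = np.random.default_rng(9)
        resid = rng.normal(size=(6, 12))
        basis = gene_correlation_eigen(resid, K_max=6)
        assert basis.eigenvalues.sum() <= 6 + 1e-8


class TestBhFdrAdjust:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_fdr_adjust([0.05]), [0.05])

    def test_equal_spacing_collapses(self):
        np.testing.assert_allclose(
            bh_fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_fixed_point(self):
        np.testing.assert_allclose(bh_fdr_adjust([0.5] * 10), [0.5] * 10)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr_adjust([0.1, 1.5])
        with pytest.raises(ValidationError):
            bh_fdr_adjust([-0.1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_bruteforce_and_statsmodels(self, pvals):
        mine = bh_fdr_adjust(pvals)
        assert np.array_equal(mine, bh_stepup_bruteforce(pvals))
        from statsmodels.stats.multitest import multipletests

        _, sm, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(mine, sm, atol=1e-12)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        adj = bh_fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _sim_matrix(seed=0, G=4, n=10, delta=0.0):
    rng = np.random.default_rng(seed)
    group = np.array(["control"] * (n // 2) + ["case"] * (n - n // 2))
    values = rng.normal(7.0, 0.5, size=(G, n)) + 0.3 * rng.normal(size=n)
    values[:, group == "case"] += delta
    samples = [f"S{i}" for i in range(n)]
    matrix = ExpressionMatrix([f"G{i}" for i in range(G)], samples, values)
    batch = [f"B{i % 2}" for i in range(n)]
    meta = SampleMetadata(samples, group, batch, samples)
    return matrix, meta


class TestFitGeneSetModel:
    def test_constant_data_degenerate(self):
        samples = ["S1", "S2", "S3", "S4"]
        matrix = ExpressionMatrix(["G1", "G2"], samples, np.full((2, 4), 3.0))
        meta = SampleMetadata(
            samples, ["control", "control", "case", "case"], ["B1"] * 4, samples
        )
        with pytest.raises(DegenerateDataError):
            fit_gene_set_model(["G1", "G2"], matrix, meta, min_size=2)

    @pytest.mark.parametrize("test", ["t", "wald", "lrt"])
    def test_group_swap_negates_beta_preserves_p(self, test):
        matrix, meta = _sim_matrix(seed=21, delta=0.4)
        spec = ModelSpec(test=test)
        res = fit_gene_set_model(matrix.gene_ids, matrix, meta, spec, min_size=2)
        flipped = SampleMetadata(
            meta.samples,
            np.where(meta.group == "case", "control", "case"),
            meta.batch,
            meta.subject,
        )
        res2 = fit_gene_set_model(matrix.gene_ids, matrix, meta=flipped, spec=spec, min_size=2)
        assert res2.beta_hat == pytest.approx(-res.beta_hat, abs=1e-6)
        assert res2.raw_p == pytest.approx(res.raw_p, abs=1e-8)

    def test_sample_permutation_invariance(self):
        matrix, meta = _sim_matrix(seed=22, delta=0.3)
        res = fit_gene_set_model(matrix.gene_ids, matrix, meta, min_size=2)
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.n_samples)
        matrix2 = ExpressionMatrix(
            matrix.gene_ids,
            [matrix.sample_ids[i] for i in perm],
            matrix.values[:, perm],
        )
        meta2 = SampleMetadata(
            [meta.samples[i] for i in perm],
            meta.group[perm],
            meta.batch[perm],
            meta.subject[perm],
        )
        res2 = fit_gene_set_model(matrix.gene_ids, matrix2, meta2, min_size=2)
        assert res2.raw_p == pytest.approx(res.raw_p, abs=1e-8)
        assert res2.beta_hat == pytest.approx(res.beta_hat, abs=1e-8)

    def test_variance_components_nonnegative(self):
        matrix, meta = _sim_matrix(seed=23)
        res = fit_gene_set_model(matrix.gene_ids, matrix, meta, min_size=2)
        vc = res.var_components
        assert vc["residual"] > 0
        assert vc["batch"] >= 0 and vc["subject"] >= 0
        assert np.all(vc["eigen"] >= 0)

    def test_zero_variance_gene_dropped_with_warning(self):
        matrix, meta = _sim_matrix(seed=24, G=4)
        values = matrix.values.copy()
        values[1] = 5.0  # flat gene
        matrix = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, values)
        with pytest.warns(UserWarning, match="G1"):
            res = fit_gene_set_model(matrix.gene_ids, matrix, meta, min_size=2)
        assert np.isfinite(res.raw_p)

    def test_min_size_enforced(self):
        matrix, meta = _sim_matrix(seed=25, G=3)
        with pytest.raises(ValidationError, match="min_size"):
            fit_gene_set_model(["G0", "G1"], matrix, meta, min_size=5)


class TestScreenGeneSets:
    def test_single_set_fdr_equals_raw(self, small_dataset):
        matrix, meta, collection, _ = small_dataset
        one = GeneSetCollection([collection.sets()[0]])
        table = screen_gene_sets(one, matrix, meta)
        assert len(table) == 1
        assert table.results[0].fdr_p == pytest.approx(table.results[0].raw_p)

    def test_sorted_by_raw_p_with_name_ties(self, small_dataset):
        matrix, meta, collection, _ = small_dataset
        genes = collection.sets()[0].genes
        # two sets over identical data differ only by name -> name order
        dup = GeneSetCollection(
            [GeneSet("ZZZ_COPY", "na", genes), GeneSet("AAA_COPY", "na", genes)]
        )
        table = screen_gene_sets(dup, matrix, meta)
        assert [r.set_name for r in table.results] == ["AAA_COPY", "ZZZ_COPY"]
        assert table.results[0].raw_p == pytest.approx(table.results[1].raw_p, abs=1e-12)

    def test_table_layout_and_fdr_family(self, small_dataset, tmp_path):
        matrix, meta, collection, _ = small_dataset
        table = screen_gene_sets(collection, matrix, meta)
        df = table.to_dataframe()
        assert list(df.columns) == ["set_name", "size", "raw_p", "fdr_p", "beta_hat", "converged"]
        assert len(df) == len(collection)
        np.testing.assert_allclose(
            np.sort(df.fdr_p.to_numpy()),
            np.sort(bh_fdr_adjust(df.raw_p.to_numpy())),
            atol=1e-12,
        )
        assert (df.fdr_p >= df.raw_p - 1e-12).all()
        assert df.raw_p.is_monotonic_increasing
        out = tmp_path / "screen.tsv"
        table.write(out)
        header = out.read_text().splitlines()[0]
        assert header == "set_name\tsize\traw_p\tfdr_p\tbeta_hat\tconverged"

    def test_no_surviving_sets_is_error(self, small_dataset):
        matrix, meta, _, _ = small_dataset
        foreign = GeneSetCollection([GeneSet("S", "na", ("NOPE1", "NOPE2", "NOPE3", "NOPE4", "NOPE5"))])
        with pytest.raises(ValidationError):
            screen_gene_sets(foreign, matrix, meta)

    def test_size_is_post_intersection_count(self, small_dataset):
        matrix, meta, collection, _ = small_dataset
        gs = collection.sets()[0]
        padded = GeneSetCollection([GeneSet(gs.name, "na", gs.genes + ("UNMEASURED1", "UNMEASURED2"))])
        table = screen_gene_sets(padded, matrix, meta)
        assert table.results[0].size == gs.size
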