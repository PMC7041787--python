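import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import comb

from crossomics import methylqtl
from crossomics.dataio import MatrixTable
from crossomics.errors import ConfigError


class TestMvalue:
    @pytest.mark.parametrize("beta, expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_closed_form(self, beta, expected):
        assert methylqtl.mvalue(beta) == pytest.approx(expected)

    def test_symmetry(self):
        b = np.linspace(0.05, 0.95, 19)
        assert np.allclose(methylqtl.mvalue(b), -methylqtl.mvalue(1 - b))

    def test_boundary_clamped_finite(self):
        assert np.isfinite(methylqtl.mvalue([0.0, 1.0])).all()


def _random_m(n_cpg=40, n_cases=30, n_controls=30, seed=0, delta=0.0):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    case = np.r_[np.ones(n_cases), np.zeros(n_controls)]
    m = rng.standard_normal((n_cpg, n))
    m[: n_cpg // 2] += delta * case
    mat = MatrixTable(values=pd.DataFrame(
        m, index=[f"cg{i}" for i in range(n_cpg)],
        columns=[f"s{i}" for i in range(n)],
    ))
    return mat, case


class TestDmpTest:
    def test_matches_pooled_t_test_without_covariates(self):
        mat, case = _random_m(seed=1)
        res = methylqtl.dmp_test(mat, case)
        x = mat.values.to_numpy()
        t_ref, p_ref = stats.ttest_ind(x[:, case == 1], x[:, case == 0], axis=1)
        assert np.allclose(np.abs(res.rows["t"]), np.abs(t_ref), atol=1e-10)
        assert np.allclose(res.rows["p"], p_ref, atol=1e-10)

    def test_matches_statsmodels_with_covariates(self):
        # dual route: closed-form vectorized OLS vs statsmodels per CpG
        mat, case = _random_m(n_cpg=5, seed=2)
        rng = np.random.default_rng(3)
        cov = pd.DataFrame(
            {"age": rng.uniform(20, 70, len(case)), "sex": rng.integers(0, 2, len(case))},
            index=mat.values.columns,
        )
        res = methylqtl.dmp_test(mat, case, cov)
        x = sm.add_constant(np.column_stack([case, cov.to_numpy()]))
        for i, cpg in enumerate(mat.values.index):
            fit = sm.OLS(mat.values.iloc[i].to_numpy(), x).fit()
            assert res.rows.loc[cpg, "estimate"] == pytest.approx(fit.params[1], rel=1e-8)
            assert res.rows.loc[cpg, "p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_permuted_labels_give_uniform_p(self):
        mat, case = _random_m(n_cpg=300, seed=4, delta=1.5)
        rng = np.random.default_rng(5)
        res = methylqtl.dmp_test(mat, rng.permutation(case))
        assert stats.kstest(res.rows["p"].dropna(), "uniform").pvalue > 0.01

    def test_zero_variance_row_flagged_untestable(self):
        mat, case = _random_m(n_cpg=10, seed=6)
        vals = mat.values.copy()
        vals.iloc[0] = 3.14
        res = methylqtl.dmp_test(MatrixTable(values=vals), case)
        assert res.n_tests == 9
        assert np.isnan(res.rows.iloc[0]["p"])
        assert not res.rows.iloc[0]["significant"]
        assert res.threshold == pytest.approx(0.05 / 9)

    def test_affine_response_rescaling_preserves_p(self):
        mat, case = _random_m(seed=7)
        res1 = methylqtl.dmp_test(mat, case)
        scaled = MatrixTable(values=mat.values * 3.0 + 11.0)
        res2 = methylqtl.dmp_test(scaled, case)
        assert np.allclose(res1.rows["p"], res2.rows["p"], atol=1e-12)

    def test_too_few_samples_per_group_rejected(self):
        mat, _ = _random_m(n_cases=1, n_controls=5)
        with pytest.raises(ConfigError):
            methylqtl.dmp_test(mat, np.r_[1, np.zeros(5)])


class TestBinomialConsistency:
    def test_direct_tail_summation_oracle(self):
        # independent oracle: doubled exact tail at p0 = 1/2
        for k, n in [(34, 38), (9, 10), (60, 100)]:
            tail = sum(comb(n, i, exact=True) for i in range(k, n + 1)) / 2 ** n
            expected = min(1.0, 2 * tail)
            assert methylqtl.binomial_consistency(k, n) == pytest.approx(
                expected, rel=1e-9
            )

    def test_central_value_is_one(self):
        assert methylqtl.binomial_consistency(5, 10) == pytest.approx(1.0)

    def test_symmetry_under_complement(self):
        for k, n, p0 in [(3, 10, 0.3), (7, 12, 0.6), (0, 5, 0.2)]:
            assert methylqtl.binomial_consistency(k, n, p0) == pytest.approx(
                methylqtl.binomial_consistency(n - k, n, 1 - p0), rel=1e-9
            )

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            methylqtl.binomial_consistency(11, 10)


class TestConvergenceFilter:
    def _dmp_all_significant(self, cpgs):
        rows = pd.DataFrame(
            {"estimate": 1.0, "t": 10.0, "p": 1e-12, "significant": True},
            index=cpgs,
        )
        return methylqtl.DmpResult(rows=rows, n_tests=len(cpgs), threshold=1e-6)

    def test_all_genes_significant_closes_stages(self):
        genes = [f"G{i}" for i in range(6)]
        cpg_map = pd.DataFrame(
            {"cpg_id": [f"cg{i}" for i in range(6)], "gene_id": genes,
             "chrom": "1", "pos": 100}
        )
        dmp = self._dmp_all_significant(cpg_map["cpg_id"])
        ev = pd.Series(2, index=genes)
        res = methylqtl.convergence_filter(genes, genes, ev, dmp, cpg_map)
        assert res.stage3_of_stage1 == res.stage1
        n = len(res.stage1)
        assert res.binomial_p_stage1 == pytest.approx(min(1.0, 2 * 0.5 ** n))

    def test_empty_stage1_skips_binomials(self):
        cpg_map = pd.DataFrame(columns=["cpg_id", "gene_id", "chrom", "pos"])
        dmp = self._dmp_all_significant([])
        res = methylqtl.convergence_filter(
            ["G1"], ["G2"], pd.Series(dtype=float), dmp, cpg_map
        )
        assert res.status == "skipped"
        assert res.binomial_p_stage1 is None

    def test_planted_corpus_stages_match_set_algebra(self, corpus):
        truth = corpus.truth
        module_genes = {g for g, m in truth.module_assignment.items() if m > 0}
        m_mat = MatrixTable(values=pd.DataFrame(
            methylqtl.mvalue(corpus.methylation.values.to_numpy()),
            index=corpus.methylation.values.index,
            columns=corpus.methylation.values.columns,
        ))
        dmp = methylqtl.dmp_test(
            m_mat, corpus.meth_samples["case"], corpus.meth_samples[["age", "sex"]]
        )
        ev = corpus.meth_evidence.set_index("gene_id")["n_evidence"]
        res = methylqtl.convergence_filter(
            module_genes, truth.smoking_meth_genes, ev, dmp, corpus.cpg_map
        )
        # oracle: the same set algebra on the planted flags
        expected_stage1 = module_genes & set(truth.smoking_meth_genes)
        assert res.stage1 == expected_stage1
        well_supported = set(ev.index[ev >= 2])
        assert res.stage2 == expected_stage1 & well_supported
        # planted effects are large: detected methylation genes = planted ones
        assert res.stage3_of_stage1 == expected_stage1 & set(truth.dmp_genes)


class TestLdExpand:
    def _geno(self, dosages, positions):
        ids = [f"s{i}" for i in range(len(dosages))]
        meta = pd.DataFrame(
            {"chrom": "1", "pos": positions}, index=pd.Index(ids, name="snp_id")
        )
        values = pd.DataFrame(
            np.asarray(dosages, dtype=float), index=ids,
            columns=[f"ind{j}" for j in range(len(dosages[0]))],
        )
        return MatrixTable(values=values, row_meta=meta)

    def test_tag_always_included(self):
        geno = self._geno([[0, 1, 2, 1], [2, 1, 0, 1]], [100, 200])
        assert "s0" in methylqtl.ld_expand(["s0"], geno)

    def test_duplicated_dosage_column_always_included(self):
        geno = self._geno([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]], [100, 500])
        assert methylqtl.ld_expand(["s0"], geno) == {"s0", "s1"}

    def test_independent_snps_rarely_join(self):
        rng = np.random.default_rng(8)
        n_snps, n = 200, 500
        dosages = rng.binomial(2, 0.3, size=(n_snps, n))
        geno = self._geno(list(dosages), list(range(100, 100 + n_snps)))
        expanded = methylqtl.ld_expand(["s0"], geno)
        false_pos = len(expanded - {"s0"})
        assert false_pos / (n_snps - 1) < 0.05


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        snps = pd.DataFrame({"chrom": ["1", "1"], "pos": [100_000, 100_000]},
                            index=pd.Index(["sA", "sB"], name="snp_id"))
        feats = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [120_000, 120_001]},
            index=pd.Index(["fA", "fB"], name="feature_id"),
        )
        pairs = methylqtl.cis_pairs(snps.iloc[:1], feats, window=20_000)
        assert pairs.to_records(index=False).tolist() == [("sA", "fA")]

    def test_different_chromosome_never_pairs(self):
        snps = pd.DataFrame({"chrom": ["1"], "pos": [500]},
                            index=pd.Index(["s"], name="snp_id"))
        feats = pd.DataFrame({"chrom": ["2"], "pos": [500]},
                             index=pd.Index(["f"], name="feature_id"))
        assert methylqtl.cis_pairs(snps, feats).empty

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(9)
        snps = pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], 100),
             "pos": rng.integers(1, 300_000, 100)},
            index=pd.Index([f"s{i}" for i in range(100)], name="snp_id"),
        )
        feats = pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], 100),
             "pos": rng.integers(1, 300_000, 100)},
            index=pd.Index([f"f{i}" for i in range(100)], name="feature_id"),
        )
        got = set(map(tuple, methylqtl.cis_pairs(snps, feats, 20_000).to_numpy()))
        expected = {
            (s, f)
            for s in snps.index for f in feats.index
            if snps.loc[s, "chrom"] == feats.loc[f, "chrom"]
            and abs(int(snps.loc[s, "pos"]) - int(feats.loc[f, "pos"])) <= 20_000
        }
        assert got == expected


class TestQtlRegression:
    def _setup(self, n=60, seed=10, slope=0.0):
        rng = np.random.default_rng(seed)
        samples = [f"i{j}" for j in range(n)]
        dose = rng.binomial(2, 0.3, size=n).astype(float)
        geno = MatrixTable(
            values=pd.DataFrame([dose], index=["snp1"], columns=samples),
            row_meta=pd.DataFrame({"chrom": ["1"], "pos": [100]}, index=["snp1"]),
        )
        y = slope * dose + rng.standard_normal(n)
        feats = MatrixTable(values=pd.DataFrame([y], index=["f1"], columns=samples))
        pairs = pd.DataFrame({"snp_id": ["snp1"], "feature_id": ["f1"]})
        return geno, feats, pairs

    def test_exact_linear_feature_recovers_slope(self):
        geno, feats, pairs = self._setup(seed=11)
        feats.values.loc["f1"] = 2.0 * geno.values.loc["snp1"]
        res = methylqtl.qtl_regression(geno, feats, pairs)
        row = res.rows.iloc[0]
        assert row["beta"] == pytest.approx(2.0)
        assert row["p"] < 1e-30

    def test_matches_statsmodels(self):
        geno, feats, pairs = self._setup(seed=12, slope=0.4)
        res = methylqtl.qtl_regression(geno, feats, pairs)
        x = sm.add_constant(geno.values.loc["snp1"].to_numpy())
        fit = sm.OLS(feats.values.loc["f1"].to_numpy(), x).fit()
        assert res.rows.iloc[0]["beta"] == pytest.approx(fit.params[1], rel=1e-8)
        assert res.rows.iloc[0]["p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_permuted_dosage_gives_uniform_p(self):
        rng = np.random.default_rng(13)
        n, n_pairs = 80, 300
        samples = [f"i{j}" for j in range(n)]
        doses = rng.binomial(2, 0.4, size=(n_pairs, n)).astype(float)
        geno = MatrixTable(
            values=pd.DataFrame(doses, index=[f"s{i}" for i in range(n_pairs)],
                                columns=samples),
            row_meta=pd.DataFrame({"chrom": "1", "pos": range(n_pairs)},
                                  index=[f"s{i}" for i in range(n_pairs)]),
        )
        feats = MatrixTable(
            values=pd.DataFrame(rng.standard_normal((n_pairs, n)),
                                index=[f"f{i}" for i in range(n_pairs)],
                                columns=samples)
        )
        pairs = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n_pairs)],
                              "feature_id": [f"f{i}" for i in range(n_pairs)]})
        res = methylqtl.qtl_regression(geno, feats, pairs)
        assert stats.kstest(res.rows["p"], "uniform").pvalue > 0.01

    def test_monomorphic_snp_skipped(self):
        geno, feats, pairs = self._setup(seed=14)
        geno.values.loc["snp1"] = 1.0
        res = methylqtl.qtl_regression(geno, feats, pairs)
        assert res.rows.empty
        assert res.skipped == [("snp1", "f1")]

    def test_significant_set_shrinks_with_fdr_cut(self, corpus):
        m_mat = MatrixTable(values=pd.DataFrame(
            methylqtl.mvalue(corpus.methylation.values.to_numpy()),
            index=corpus.methylation.values.index,
            columns=corpus.methylation.values.columns,
        ))
        feat_meta = corpus.cpg_map.rename(columns={"cpg_id": "feature_id"})[
            ["feature_id", "chrom", "pos"]
        ]
        pairs = methylqtl.cis_pairs(corpus.genotypes.row_meta, feat_meta, 20_000)
        loose = methylqtl.qtl_regression(corpus.genotypes, m_mat, pairs, fdr_cut=0.05)
        strict = methylqtl.qtl_regression(corpus.genotypes, m_mat, pairs, fdr_cut=0.001)
        assert set(strict.significant.index) <= set(loose.significant.index)
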