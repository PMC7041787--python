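import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossomics import integrate
from crossomics.errors import ConfigError, ConsistencyError

from conftest import small_config


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestAnovaScreen:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.standard_normal((30, 20)))
        groups = ["a"] * 10 + ["b"] * 10
        table, _ = integrate.anova_screen(expr, groups)
        t, p_t = stats.ttest_ind(
            expr.iloc[:, :10].to_numpy(), expr.iloc[:, 10:].to_numpy(), axis=1
        )
        assert np.allclose(table["F"], t ** 2, atol=1e-10)
        assert np.allclose(table["p"], p_t, atol=1e-10)

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.standard_normal((2000, 24)))
        groups = ["a", "b", "c", "d"] * 6
        table, _ = integrate.anova_screen(expr, groups)
        frac = (table["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_permuted_labels_give_uniform_p(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.standard_normal((500, 32)))
        expr.iloc[:, :8] += 1.0  # real group effect…
        groups = rng.permutation(["a"] * 8 + ["b"] * 8 + ["c"] * 8 + ["d"] * 8)
        table, _ = integrate.anova_screen(expr, list(groups))  # …destroyed by shuffle
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01

    def test_tukey_only_for_significant_genes(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.standard_normal((40, 24)))
        expr.iloc[0, :6] += 5.0  # one strong gene
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6 + ["d"] * 6
        table, tukey = integrate.anova_screen(expr, groups)
        assert set(tukey) == set(table.index[table["p"] < 0.05])
        assert "g0" in tukey
        pair = tukey["g0"]
        assert set(pair.columns) == {"group1", "group2", "diff", "p_adj"}

    def test_small_group_error_names_group(self):
        expr = _expr(np.ones((3, 5)))
        with pytest.raises(ConfigError, match="tiny"):
            integrate.anova_screen(expr, ["a", "a", "b", "b", "tiny"])


class TestDoseAnova:
    def test_planted_decreasing_gene_detected_with_negative_trend(self):
        rng = np.random.default_rng(4)
        doses = [0.0] * 6 + [10.0] * 6 + [100.0] * 6
        expr = _expr(rng.standard_normal((20, 18)) * 0.5)
        ranks = np.array([0] * 6 + [1] * 6 + [2] * 6, dtype=float)
        expr.iloc[0] = -1.2 * ranks + rng.standard_normal(18) * 0.3
        table = integrate.dose_anova(expr, doses)
        assert table.iloc[0]["p"] < 0.05
        assert table.iloc[0]["trend"] == -1.0

    def test_flat_genes_rarely_significant(self):
        rng = np.random.default_rng(5)
        doses = [0.0] * 8 + [1.0] * 8 + [2.0] * 8
        expr = _expr(rng.standard_normal((400, 24)))
        table = integrate.dose_anova(expr, doses)
        assert (table["p"] < 0.05).mean() < 0.1

    def test_single_dose_level_rejected(self):
        expr = _expr(np.ones((2, 4)))
        with pytest.raises(ConfigError):
            integrate.dose_anova(expr, [1.0, 1.0, 1.0, 1.0])


class TestEdgeEnrichment:
    def test_query_without_edges_gives_p_one(self):
        edges = pd.DataFrame({"node_a": ["x1", "x2"], "node_b": ["x2", "x3"]})
        res = integrate.edge_enrichment(["x1", "x3"], edges, n_iter=200, seed=0)
        assert res.observed == 0.0
        assert res.p == 1.0

    def test_planted_clique_detected_in_random_background(self):
        rng = np.random.default_rng(6)
        nodes = [f"n{i}" for i in range(200)]
        edges = set()
        n_bg = int(0.01 * len(nodes) * (len(nodes) - 1) / 2)
        while len(edges) < n_bg:
            i, j = rng.integers(0, len(nodes), 2)
            if i != j:
                edges.add(tuple(sorted((nodes[i], nodes[j]))))
        clique = [f"n{i}" for i in range(15)]
        for i in range(15):
            for j in range(i + 1, 15):
                edges.add((clique[i], clique[j]))
        df = pd.DataFrame(sorted(edges), columns=["node_a", "node_b"])
        # analytic sanity oracle: null expectation p*C(15,2) ≈ 1 edge << 105
        res = integrate.edge_enrichment(clique, df, n_iter=10_000, seed=6)
        assert res.p <= 0.01

    def test_row_order_does_not_change_result(self):
        rng = np.random.default_rng(7)
        edges = pd.DataFrame(
            {"node_a": [f"a{i}" for i in range(20)],
             "node_b": [f"a{(i + 3) % 20}" for i in range(20)]}
        )
        shuffled = edges.sample(frac=1, random_state=1).reset_index(drop=True)
        r1 = integrate.edge_enrichment(["a0", "a3", "a6"], edges, 500, seed=2)
        r2 = integrate.edge_enrichment(["a0", "a3", "a6"], shuffled, 500, seed=2)
        assert r1 == r2


class TestEvidenceMatrix:
    def _base_kwargs(self):
        return dict(
            module_labels=pd.Series({"G1": 1, "G2": 2, "G3": 0}),
            smoking_meth_genes={"G1", "G2"},
            scz_meth_genes={"G1"},
            meqtl_genes={"G1"},
            subnetwork_genes={"G1", "G2"},
            de_pvalues=pd.Series({"G1": 0.01, "G2": 0.2}),
            drug_pvalues=pd.DataFrame(
                {"quetiapine": {"G1": 0.001, "G2": 0.6},
                 "nicotine": {"G1": 0.2, "G2": 0.7}}
            ),
            literature_flags=pd.Series({"G1": True}),
        )

    def test_gene_with_no_evidence_scores_zero(self):
        ev = integrate.build_evidence_matrix(["G9"], pd.Series(dtype=int),
                                             set(), set(), set(), set())
        row = ev.loc["G9"]
        assert row["evidence_count"] == 0
        assert not row["candidate"]

    def test_candidate_requires_both_methylation_flags(self):
        ev = integrate.build_evidence_matrix(["G1", "G2", "G3"], **self._base_kwargs())
        assert bool(ev.loc["G1", "candidate"])
        assert not ev.loc["G2", "candidate"]  # smoking only
        assert not ev.loc["G3", "candidate"]

    def test_evidence_count_equals_true_boolean_columns(self):
        ev = integrate.build_evidence_matrix(["G1", "G2", "G3"], **self._base_kwargs())
        for g in ev.index:
            assert ev.loc[g, "evidence_count"] == sum(
                bool(ev.loc[g, c]) for c in integrate.EVIDENCE_COLUMNS
            )

    def test_drug_column_reports_min_p_with_label(self):
        ev = integrate.build_evidence_matrix(["G1"], **self._base_kwargs())
        assert ev.loc["G1", "drug_anova_p"] == pytest.approx(0.001)
        assert ev.loc["G1", "drug"] == "quetiapine"

    def test_removing_meqtl_input_flips_only_that_column(self):
        kwargs = self._base_kwargs()
        full = integrate.build_evidence_matrix(["G1", "G2"], **kwargs)
        kwargs["meqtl_genes"] = set()
        without = integrate.build_evidence_matrix(["G1", "G2"], **kwargs)
        assert not without["cis_meqtl"].any()
        unchanged = [c for c in full.columns
                     if c not in ("cis_meqtl", "evidence_count")]
        pd.testing.assert_frame_equal(full[unchanged], without[unchanged])

    def test_duplicate_module_assignment_rejected(self):
        labels = pd.Series([1, 2], index=["G1", "G1"])
        with pytest.raises(ConsistencyError, match="G1"):
            integrate.build_evidence_matrix(["G1"], labels, set(), set(),
                                            set(), set())

    def test_ranked_by_evidence_then_gene_id(self):
        ev = integrate.build_evidence_matrix(["G1", "G2", "G3"], **self._base_kwargs())
        counts = ev["evidence_count"].to_numpy()
        assert (np.diff(counts) <= 0).all()


@pytest.fixture(scope="module")
def result():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return integrate.run_all(small_config(seed=21), n_iter=500)


class TestRunAll:

    def test_same_seed_reproduces_summary_and_evidence(self, result):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = integrate.run_all(small_config(seed=21), n_iter=500)
        assert again.summary == result.summary
        pd.testing.assert_frame_equal(again.evidence, result.evidence)

    def test_planted_shared_pathways_recovered(self, result):
        truth_shared = set(result.corpus.truth.causal_pathways["SCZ"])
        assert truth_shared <= result.shared_all

    def test_candidate_set_matches_ground_truth_construction(self, result):
        assert sorted(result.candidate_genes) == sorted(
            result.corpus.truth.candidate_genes
        )

    def test_null_phenotype_less_enriched_than_disease(self, result):
        n = result.summary["n_enriched"]
        assert n["null"] < n["SCZ"]

    def test_similarity_separates_controls_from_disease_axis(self, result):
        sim = result.similarity
        smoking_cor = sim.loc["SCZ", ["CPD", "ever_smoking"]].mean()
        assert sim.loc["SCZ", "null"] < smoking_cor

    def test_report_files_written(self, tmp_path):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            integrate.run_all(small_config(seed=22), n_iter=200, outdir=tmp_path)
        for name in ("evidence_matrix.tsv", "summary.json", "dmp.tsv",
                     "qtl_pairs.tsv", "phenotype_similarity.tsv"):
            assert (tmp_path / name).exists()
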