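"""Group/dose ANOVA screens, network edge enrichment, the per-gene
evidence matrix with the candidate call, and the end-to-end pipeline over
a synthetic corpus.

The candidate rule is the convergence intersection: a gene is a candidate
when it carries both smoking-associated and disease-associated methylation
evidence; the remaining columns (co-expression module, cis-meQTL,
subnetwork membership, differential- and drug-expression ANOVA,
literature) feed the per-gene evidence count used for ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import coexpress, enrich, genescore, methylqtl, pathmds
from .dataio import MatrixTable
from .errors import ConfigError, ConsistencyError
from .permute import (
    PermutationResult,
    count_in_set_statistic,
    exceedance_permutation,
    overlap_permutation,
)
from .simulate import SMOKING_PHENOTYPES, SimConfig, SimCorpus, simulate_corpus


# ---------------------------------------------------------------------------
# ANOVA screens
# ---------------------------------------------------------------------------

def anova_screen(
    expr: pd.DataFrame,
    groups,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One-way ANOVA per gene across >= 2 groups, plus Tukey HSD pairwise
    comparisons for genes passing ANOVA at ``alpha``.

    Returns (per-gene frame with F and p, {gene: Tukey table}).
    """
    groups = pd.Series(list(groups), index=expr.columns)
    level_cols = {g: expr.columns[groups == g] for g in groups.unique()}
    small = [g for g, cols in level_cols.items() if len(cols) < 2]
    if small:
        raise ConfigError(f"group(s) with < 2 samples: {small}")
    if len(level_cols) < 2:
        raise ConfigError("need >= 2 groups")
    blocks = [expr[cols].to_numpy() for cols in level_cols.values()]
    f, p = stats.f_oneway(*blocks, axis=1)
    table = pd.DataFrame({"F": f, "p": p}, index=expr.index)

    tukey: dict[str, pd.DataFrame] = {}
    names = list(level_cols)
    for gene in table.index[table["p"] < alpha]:
        res = stats.tukey_hsd(*[expr.loc[gene, cols].to_numpy()
                                for cols in level_cols.values()])
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append((names[i], names[j],
                             float(res.statistic[i, j]), float(res.pvalue[i, j])))
        tukey[gene] = pd.DataFrame(rows, columns=["group1", "group2", "diff", "p_adj"])
    return table, tukey


def dose_anova(expr: pd.DataFrame, dose_labels) -> pd.DataFrame:
    """One-way ANOVA across dose groups plus a monotone-trend sign.

    The trend sign is the sign of the OLS slope of per-dose mean expression
    on dose rank; the p-value is the ANOVA p.
    """
    doses = pd.Series(list(dose_labels), index=expr.columns)
    levels = sorted(doses.unique())
    if len(levels) < 2:
        raise ConfigError("need >= 2 dose levels")
    blocks = [expr[expr.columns[doses == d]].to_numpy() for d in levels]
    if min(b.shape[1] for b in blocks) < 2:
        raise ConfigError("need >= 2 samples per dose level")
    f, p = stats.f_oneway(*blocks, axis=1)
    rank = np.arange(len(levels), dtype=float)
    means = np.column_stack([b.mean(axis=1) for b in blocks])
    rank_c = rank - rank.mean()
    slope = (means * rank_c).sum(axis=1) / (rank_c ** 2).sum()
    return pd.DataFrame(
        {"F": f, "p": p, "trend": np.sign(slope)}, index=expr.index
    )


# ---------------------------------------------------------------------------
# network edge enrichment
# ---------------------------------------------------------------------------

def _edges_among(nodes, adj: dict[str, set]) -> int:
    s = set(nodes)
    return sum(len(adj.get(g, set()) & s) for g in s) // 2


def edge_enrichment(
    query_genes,
    edges: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for edge-count enrichment among query genes.

    observed = number of network edges with both ends in the query set;
    the null redraws equally sized gene sets uniformly from the network's
    nodes.
    """
    adj: dict[str, set] = {}
    for a, b in edges.iloc[:, :2].itertuples(index=False):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)
    query = sorted(set(query_genes) & set(nodes))
    observed = _edges_among(query, adj)
    return exceedance_permutation(
        universe=nodes,
        draw_size=len(query),
        statistic=lambda draw: _edges_among(draw, adj),
        observed_count=observed,
        n_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evidence matrix
# ---------------------------------------------------------------------------

#: boolean evidence columns counted toward evidence_count
EVIDENCE_COLUMNS = (
    "in_module",
    "smoking_methylation",
    "scz_methylation",
    "cis_meqtl",
    "subnetwork",
    "de_significant",
    "drug_significant",
    "literature",
)


def build_evidence_matrix(
    genes,
    module_labels: pd.Series,
    smoking_meth_genes,
    scz_meth_genes,
    meqtl_genes,
    subnetwork_genes,
    de_pvalues: pd.Series | None = None,
    drug_pvalues: pd.DataFrame | None = None,
    literature_flags: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Join all upstream evidence by gene id.

    ``drug_pvalues`` is a gene x drug frame; the reported drug column is the
    minimum p with its drug label.  candidate = smoking_methylation AND
    scz_methylation; evidence_count = number of true boolean columns.  The
    result is ranked by evidence_count (descending) then gene id.
    """
    if module_labels.index.duplicated().any():
        dup = module_labels.index[module_labels.index.duplicated()][0]
        raise ConsistencyError(f"gene {dup!r} present in two module assignments")
    genes = sorted(set(genes))
    df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    df["module"] = module_labels.reindex(genes).fillna(0).astype(int)
    df["in_module"] = df["module"] > 0
    df["smoking_methylation"] = df.index.isin(set(smoking_meth_genes))
    df["scz_methylation"] = df.index.isin(set(scz_meth_genes))
    df["cis_meqtl"] = df.index.isin(set(meqtl_genes))
    df["subnetwork"] = df.index.isin(set(subnetwork_genes))
    de = (de_pvalues.reindex(genes) if de_pvalues is not None
          else pd.Series(np.nan, index=genes))
    df["de_anova_p"] = de
    df["de_significant"] = de < alpha
    if drug_pvalues is not None and len(drug_pvalues.columns):
        dp = drug_pvalues.reindex(genes)
        has = dp.notna().any(axis=1)
        df["drug_anova_p"] = dp.min(axis=1)
        drug = pd.Series("", index=dp.index, dtype=object)
        if has.any():
            drug[has] = dp[has].idxmin(axis=1)
        df["drug"] = drug
    else:
        df["drug_anova_p"] = np.nan
        df["drug"] = ""
    df["drug_significant"] = df["drug_anova_p"] < alpha
    lit = (literature_flags.reindex(genes).astype("boolean").fillna(False).astype(bool)
           if literature_flags is not None else pd.Series(False, index=genes))
    df["literature"] = lit
    df["evidence_count"] = df[list(EVIDENCE_COLUMNS)].sum(axis=1).astype(int)
    df["candidate"] = df["smoking_methylation"] & df["scz_methylation"]
    return df.sort_values(["evidence_count", "gene_id"],
                          ascending=[False, True], kind="mergesort")


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    corpus: SimCorpus
    gene_scores: dict[str, genescore.GeneScoreTable]
    enrichment: dict[str, enrich.EnrichmentResult]
    shared_all: set[str]
    shared_any: set[str]
    similarity: pd.DataFrame
    embedding: pathmds.PathwayEmbedding | None
    overlap_test: PermutationResult
    modules: coexpress.CoexpressionModules
    module_flags: pd.DataFrame
    dmp: methylqtl.DmpResult
    convergence: methylqtl.ConvergenceResult
    qtl: methylqtl.QtlPairs
    de_table: pd.DataFrame
    dose_tables: dict[str, pd.DataFrame]
    drug_exceedance: dict[str, dict[str, PermutationResult]]
    ppi_test: PermutationResult
    evidence: pd.DataFrame
    summary: dict = field(default_factory=dict)

    @property
    def candidate_genes(self) -> list[str]:
        return sorted(self.evidence.index[self.evidence["candidate"]])


def run_all(
    config: SimConfig | None = None,
    q_cut: float = 0.1,
    window: int = 20_000,
    fdr_cut: float = 0.01,
    alpha: float = 0.05,
    k_clusters: int = 5,
    n_iter: int = 10_000,
    min_module_size: int = 30,
    cut_height: float = 0.9,
    outdir=None,
) -> PipelineResult:
    """Run every stage of the convergence analysis on a synthetic corpus.

    Fully deterministic for a fixed ``config.seed``: rerunning writes a
    byte-identical report.
    """
    config = config or SimConfig()
    corpus = simulate_corpus(config)
    seed = config.seed

    # --- GWAS gene scores and pathway enrichment -------------------------
    any_gwas = next(iter(corpus.gwas.values()))
    assignment = genescore.assign_snps_to_genes(any_gwas, corpus.annotation, window)
    scores = {
        ph: genescore.gene_scores(g, assignment, corpus.annotation)
        for ph, g in corpus.gwas.items()
    }
    results = {ph: enrich.enrich_phenotype(t, corpus.pathways)
               for ph, t in scores.items()}
    disease_results = [results["SCZ"]] + [results[ph] for ph in SMOKING_PHENOTYPES]
    shared_all = enrich.shared_pathways(disease_results, "SCZ", "all", q_cut)
    shared_any = enrich.shared_pathways(disease_results, "SCZ", "any", q_cut)
    zmat = enrich.z_matrix(list(results.values()))
    similarity = enrich.phenotype_similarity(zmat)

    # --- MDS + clustering of the shared pathways -------------------------
    embedding = None
    if len(shared_all) >= 3:
        embedding = pathmds.embed_pathways(
            corpus.pathways, sorted(shared_all), dims=2,
            k=min(k_clusters, len(shared_all))
        )

    # --- overlap of gene-based hits with shared-pathway genes ------------
    universe = sorted(corpus.pathways.gene_universe())
    shared_any_genes = (
        set().union(*[corpus.pathways.genes(p) for p in shared_any])
        if shared_any else set()
    )
    sig_genes = set(genescore.significant_genes(scores["SCZ"], alpha))
    drawn = sorted(shared_any_genes & set(universe))
    if drawn:
        overlap_test = overlap_permutation(
            universe, len(drawn), sig_genes & set(universe),
            n_iter=n_iter, seed=seed, drawn_set=drawn,
        )
    else:
        overlap_test = overlap_permutation(
            universe, 1, sig_genes & set(universe),
            n_iter=n_iter, seed=seed, observed=0,
        )

    # --- co-expression modules on brain development expression -----------
    brain = corpus.expression["brain"]
    beta = coexpress.pick_soft_threshold(brain.values)
    tom = coexpress.tom_similarity(brain.values, beta)
    modules = coexpress.detect_modules(
        brain.values, tom, min_module_size=min_module_size,
        cut_height=cut_height, beta=beta,
    )
    hubs = coexpress.hub_genes(modules)
    _, module_flags = coexpress.regional_profile(brain.values, modules,
                                                brain.col_meta)
    module_genes = set(modules.labels.index[modules.labels > 0])

    # --- differential methylation + convergence --------------------------
    m_mat = MatrixTable(values=pd.DataFrame(
        methylqtl.mvalue(corpus.methylation.values.to_numpy()),
        index=corpus.methylation.values.index,
        columns=corpus.methylation.values.columns,
    ))
    covs = corpus.meth_samples[["age", "sex"]]
    dmp = methylqtl.dmp_test(m_mat, corpus.meth_samples["case"], covs, alpha)
    evidence_counts = corpus.meth_evidence.set_index("gene_id")["n_evidence"]
    # the smoking-methylation panel is exactly the set of genes carrying CpGs
    smoking_meth_genes = set(corpus.cpg_map["gene_id"])
    convergence = methylqtl.convergence_filter(
        module_genes, smoking_meth_genes, evidence_counts,
        dmp, corpus.cpg_map,
    )
    scz_meth_genes = methylqtl.genes_with_significant_cpg(dmp, corpus.cpg_map)

    # --- cis-meQTL regression --------------------------------------------
    snp_meta = corpus.genotypes.row_meta[["chrom", "pos"]]
    feat_meta = corpus.cpg_map.rename(columns={"cpg_id": "feature_id"})[
        ["feature_id", "chrom", "pos"]
    ]
    pairs = methylqtl.cis_pairs(snp_meta, feat_meta, window)
    qtl = methylqtl.qtl_regression(corpus.genotypes, m_mat, pairs,
                                   covariates=covs, fdr_cut=fdr_cut,
                                   window=window)
    cpg_to_gene = corpus.cpg_map.set_index("cpg_id")["gene_id"]
    meqtl_genes = (
        set(cpg_to_gene.reindex(
            qtl.significant.index.get_level_values("feature_id")).dropna())
        if len(qtl.significant) else set()
    )

    # --- expression screens ----------------------------------------------
    cc = corpus.expression["case_control"]
    de_table, _ = anova_screen(cc.values, cc.col_meta["group"], alpha)
    dose_tables, drug_exceedance = {}, {}
    # detected candidates: evidence-filtered convergent genes that carry
    # disease-associated methylation
    candidates_guess = sorted(convergence.stage3_of_stage2)
    shared_all_genes = (
        set().union(*[corpus.pathways.genes(p) for p in shared_all])
        if shared_all else set()
    )
    for drug in config.drug_doses:
        mat = corpus.expression[f"dose:{drug}"]
        dt = dose_anova(mat.values, mat.col_meta["dose"])
        dose_tables[drug] = dt
        responsive = set(dt.index[dt["p"] < alpha])
        pools = {
            "shared_all_pathways": shared_all_genes,
            "shared_any_pathways": shared_any_genes,
            "background": set(mat.values.index),
        }
        drug_exceedance[drug] = {}
        for pool_name, pool in pools.items():
            pool_genes = sorted((pool & set(mat.values.index)) |
                                set(candidates_guess))
            query = [g for g in candidates_guess if g in set(pool_genes)]
            if len(query) == 0 or len(pool_genes) <= len(query):
                continue
            observed = sum(1 for g in query if g in responsive)
            drug_exceedance[drug][pool_name] = exceedance_permutation(
                pool_genes, len(query),
                count_in_set_statistic(responsive & set(pool_genes)),
                observed, n_iter=n_iter, seed=seed,
            )

    # --- network enrichment ----------------------------------------------
    ppi_test = edge_enrichment(candidates_guess, corpus.ppi_edges,
                               n_iter=n_iter, seed=seed)

    # --- evidence matrix ---------------------------------------------------
    subnet_adj: dict[str, set] = {}
    for a, b in corpus.ppi_edges.iloc[:, :2].itertuples(index=False):
        subnet_adj.setdefault(a, set()).add(b)
        subnet_adj.setdefault(b, set()).add(a)
    cand_set = set(candidates_guess)
    subnetwork_genes = {g for g in cand_set
                        if subnet_adj.get(g, set()) & (cand_set - {g})}
    drug_p = pd.DataFrame({d: t["p"] for d, t in dose_tables.items()})
    lit = corpus.literature.set_index("gene_id")["literature"]
    evidence = build_evidence_matrix(
        genes=sorted(convergence.stage2),
        module_labels=modules.labels,
        smoking_meth_genes=smoking_meth_genes,
        scz_meth_genes=scz_meth_genes,
        meqtl_genes=meqtl_genes,
        subnetwork_genes=subnetwork_genes,
        de_pvalues=de_table["p"],
        drug_pvalues=drug_p,
        literature_flags=lit,
        alpha=alpha,
    )

    summary = {
        "seed": seed,
        "n_pathways": len(corpus.pathways),
        "n_enriched": {ph: int((r.rows["q"] < q_cut).sum())
                       for ph, r in results.items()},
        "n_shared_all": len(shared_all),
        "n_shared_any": len(shared_any),
        "overlap_p": overlap_test.p,
        "soft_power": beta,
        "n_modules": len(modules.module_ids),
        "hubs": {str(m): h for m, h in hubs.items()},
        "n_dmp_significant": int(dmp.rows["significant"].sum()),
        "dmp_threshold": dmp.threshold,
        "convergence_counts": convergence.counts,
        "binomial_p_stage1": convergence.binomial_p_stage1,
        "binomial_p_stage2": convergence.binomial_p_stage2,
        "n_qtl_significant": int(len(qtl.significant)),
        "ppi_p": ppi_test.p,
        "n_candidates": int(evidence["candidate"].sum()),
        "candidates": sorted(evidence.index[evidence["candidate"]]),
    }

    result = PipelineResult(
        corpus=corpus, gene_scores=scores, enrichment=results,
        shared_all=shared_all, shared_any=shared_any, similarity=similarity,
        embedding=embedding, overlap_test=overlap_test, modules=modules,
        module_flags=module_flags, dmp=dmp, convergence=convergence, qtl=qtl,
        de_table=de_table, dose_tables=dose_tables,
        drug_exceedance=drug_exceedance, ppi_test=ppi_test,
        evidence=evidence, summary=summary,
    )
    if outdir is not None:
        _write_report(result, outdir)
    return result


def _write_report(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.evidence.to_csv(out / "evidence_matrix.tsv", sep="\t")
    result.similarity.to_csv(out / "phenotype_similarity.tsv", sep="\t")
    for ph, r in result.enrichment.items():
        r.rows.to_csv(out / f"enrichment_{ph}.tsv", sep="\t")
    if result.embedding is not None:
        emb = pd.DataFrame(
            result.embedding.coordinates,
            index=result.embedding.pathway_ids,
            columns=["dim1", "dim2"],
        )
        emb["cluster"] = result.embedding.cluster_labels
        emb.to_csv(out / "pathway_mds.tsv", sep="\t")
    result.dmp.rows.to_csv(out / "dmp.tsv", sep="\t")
    result.qtl.rows.to_csv(out / "qtl_pairs.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True, default=str)
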