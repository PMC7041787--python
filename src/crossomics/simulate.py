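"""Synthetic multi-omics corpus with planted ground truth.

Generates every input the convergence pipeline consumes — multi-phenotype
GWAS summary statistics with shared causal pathways, case/control
methylation with planted gene-level effects, genotype dosages with planted
cis effects, block-correlated expression matrices (brain region x stage,
four-group case/control, drug dose series), a protein-interaction edge
list, and literature flags — together with a machine-readable record of
what was planted, so every pipeline stage can be scored against truth.

The default configuration is a desk-scale analogue of a comorbidity study
design: one disease-like phenotype and four smoking-like phenotypes sharing
eight causal pathways, plus a null phenotype (no signal anywhere) and a
height-like phenotype with disjoint causal pathways as negative controls,
over 2,000 genes and 200 pathways.

All randomness flows through numpy's PCG64 generator
(``numpy.random.default_rng``); each artifact derives its stream from
``(seed, component-code)`` so a fixed seed yields byte-identical output
regardless of which artifacts are built or in what order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import (
    GeneAnnotation,
    GwasSummary,
    MatrixTable,
    Pathway,
    PathwayCollection,
    write_annotation,
    write_edge_list,
    write_gmt,
    write_gwas,
    write_matrix,
)
from .errors import ConfigError

# component codes for deriving independent PRNG streams from one seed
_STREAM = {
    "genome": 1,
    "pathways": 2,
    "gwas": 3,  # + per-phenotype offset
    "methylation": 20,
    "genotypes": 21,
    "expr_brain": 22,
    "expr_groups": 23,
    "expr_dose": 24,  # + per-drug offset
    "ppi": 30,
    "literature": 31,
}


def _rng(seed: int, component: str, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[component] + offset])


SMOKING_PHENOTYPES = ("CPD", "ever_smoking", "former_smoking", "age_initiation")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic corpus.

    Effect sizes: ``effect_lambda`` is the noncentrality of the chi-square(1)
    association signal at causal SNPs; ``meth_effect_delta`` is the case
    shift on the M-value (log2-odds) scale; ``qtl_slope`` is the per-allele
    slope on the same scale; ``de_effect`` and ``dose_slope`` are mean shifts
    on log2 expression.
    """

    seed: int = 0

    # genome
    n_genes: int = 2000
    n_chroms: int = 20
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    intergenic_gap_range: tuple[int, int] = (30_000, 80_000)
    n_snps_per_gene: tuple[int, int] = (3, 8)
    intergenic_snp_fraction: float = 0.1

    # pathways
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (10, 60)
    n_shared_causal_pathways: int = 8
    n_height_causal_pathways: int = 8

    # GWAS
    effect_lambda: float = 30.0
    phenotype_lambdas: dict = field(default_factory=dict)  # overrides per phenotype

    # methylation
    n_cases: int = 200
    n_controls: int = 200
    cpgs_per_gene: int = 5
    n_smoking_meth_genes: int = 150
    n_dmp_genes: int = 125  # most of the smoking panel is also disease-methylated
    evidence_probs: tuple[float, ...] = (0.7, 0.15, 0.1, 0.05)  # P(count = 1..4)
    meth_effect_delta: float = 2.0
    age_coef: float = 0.02  # per year of age, M-value scale
    sex_coef: float = 0.5

    # genotypes / cis-QTL
    n_geno_samples: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_qtl_pairs: int = 50
    n_null_geno_snps: int = 150
    qtl_slope: float = 1.0
    ld_rho: float = 0.0  # latent correlation within 2-SNP LD blocks; 0 = no LD
    qtl_window: int = 20_000

    # brain development expression
    module_spec: tuple[tuple[int, float], ...] = ((50, 0.8),) * 5
    n_brain_noise_genes: int = 550
    regions: tuple[str, ...] = ("FC", "TC", "STR", "CBC")
    stages: tuple[str, ...] = ("fetal", "infant", "child", "adolescent", "adult")
    reps_per_cell: int = 4
    regional_fold: float = 2.5  # planted fold change of module 1 between regions
    temporal_fold: float = 2.5  # planted fold change of module 2 across stages

    # four-group case/control expression
    n_per_group: int = 8
    n_de_genes: int = 9
    de_effect: float = 1.5
    n_cc_background_genes: int = 400

    # drug dose series
    drug_doses: dict = field(
        default_factory=lambda: {
            "quetiapine": (0.0, 10.0, 100.0),
            "nicotine": (0.0, 8.0, 15.0, 23.0),
        }
    )
    n_per_dose: int = 6
    dose_slope: float = 0.8
    candidate_responsive_frac: float = 0.7
    background_responsive_frac: float = 0.05
    n_dose_background_genes: int = 800

    # protein-interaction network
    ppi_background_p: float = 0.002
    ppi_candidate_p: float = 0.5
    ppi_n_nodes: int = 1000

    # literature flags
    literature_frac: float = 0.4

    def lam(self, phenotype: str) -> float:
        lam = self.phenotype_lambdas.get(phenotype, self.effect_lambda)
        if phenotype == "null":
            lam = self.phenotype_lambdas.get("null", 0.0)
        if lam < 0:
            raise ConfigError(f"noncentrality for {phenotype!r} must be >= 0, got {lam}")
        return lam


@dataclass
class GroundTruth:
    """What was planted, keyed the same way the pipeline outputs are."""

    causal_pathways: dict[str, list[str]]
    causal_genes: dict[str, list[str]]
    smoking_meth_genes: list[str]
    dmp_genes: list[str]
    dmp_cpgs: list[str]
    qtl_pairs: list[tuple[str, str]]
    module_assignment: dict[str, int]
    de_genes: list[str]
    drug_responsive_genes: dict[str, list[str]]
    regional_modules: list[int]
    temporal_modules: list[int]
    candidate_genes: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["qtl_pairs"] = [tuple(p) for p in d["qtl_pairs"]]
        return cls(**d)


@dataclass
class SimCorpus:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimConfig
    annotation: GeneAnnotation
    pathways: PathwayCollection
    gwas: dict[str, GwasSummary]
    methylation: MatrixTable  # CpG x sample beta values
    meth_m: MatrixTable  # same on the M-value scale (pre-logistic latent)
    meth_samples: pd.DataFrame  # sample sheet: case, age, sex
    cpg_map: pd.DataFrame  # cpg_id, gene_id, chrom, pos
    genotypes: MatrixTable  # SNP x sample dosage, row_meta chrom/pos/maf
    expression: dict[str, MatrixTable]  # brain, case_control, dose:<drug>
    ppi_edges: pd.DataFrame
    literature: pd.DataFrame  # gene_id, literature flag
    meth_evidence: pd.DataFrame  # gene_id, n_evidence (input column, never derived)
    truth: GroundTruth

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_annotation(self.annotation, out / "genes.tsv")
        write_gmt(self.pathways, out / "pathways.gmt")
        for name, g in self.gwas.items():
            write_gwas(g, out / f"gwas_{name}.tsv")
        write_matrix(self.methylation, out / "methylation_beta.tsv")
        self.meth_samples.to_csv(out / "methylation_samples.tsv", sep="\t")
        self.cpg_map.to_csv(out / "cpg_map.tsv", sep="\t", index=False)
        write_matrix(self.genotypes, out / "genotypes.tsv")
        self.genotypes.row_meta.to_csv(out / "snp_meta.tsv", sep="\t")
        for name, m in self.expression.items():
            tag = name.replace(":", "_")
            write_matrix(m, out / f"expression_{tag}.tsv")
            if m.col_meta is not None:
                m.col_meta.to_csv(out / f"expression_{tag}_samples.tsv", sep="\t")
        write_edge_list(self.ppi_edges, out / "ppi_edges.tsv")
        self.literature.to_csv(out / "literature_flags.tsv", sep="\t", index=False)
        self.meth_evidence.to_csv(out / "meth_evidence.tsv", sep="\t", index=False)
        self.truth.to_json(out / "ground_truth.json")


# ---------------------------------------------------------------------------
# genome & pathways
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> GeneAnnotation:
    """Lay out gene bodies on chromosomes with intergenic gaps."""
    rng = _rng(config.seed, "genome")
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    rows = []
    g = 0
    for c in range(1, config.n_chroms + 1):
        pos = 1
        for _ in range(per_chrom):
            if g >= config.n_genes:
                break
            gap = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
            length = int(rng.integers(*config.gene_length_range, endpoint=True))
            start = pos + gap
            end = start + length - 1
            rows.append((f"G{g:04d}", str(c), start, end,
                         "+" if rng.random() < 0.5 else "-"))
            pos = end
            g += 1
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(table=df)


def simulate_pathways(
    config: SimConfig, annotation: GeneAnnotation
) -> tuple[PathwayCollection, dict[str, list[str]]]:
    """Random gene sets plus the planted causal-pathway design.

    Returns the collection and a map phenotype -> causal pathway ids: the
    disease- and smoking-like phenotypes share one block of pathways, the
    height-like control gets a disjoint block, the null phenotype none.
    """
    rng = _rng(config.seed, "pathways")
    genes = np.array(annotation.gene_ids)
    entries: dict[str, Pathway] = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(*config.pathway_size_range, endpoint=True))
        members = rng.choice(genes, size=size, replace=False)
        entries[f"PW{i:03d}"] = Pathway(
            description=f"synthetic pathway {i}",
            source="other",
            genes=frozenset(members.tolist()),
        )
    collection = PathwayCollection(entries)
    ids = list(entries)
    n_shared, n_height = config.n_shared_causal_pathways, config.n_height_causal_pathways
    picked = rng.choice(len(ids), size=n_shared + n_height, replace=False)
    shared = [ids[i] for i in picked[:n_shared]]
    height = [ids[i] for i in picked[n_shared:]]
    causal = {"SCZ": shared, "null": [], "height": height}
    for ph in SMOKING_PHENOTYPES:
        causal[ph] = shared
    return collection, causal


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def _snp_layout(config: SimConfig, annotation: GeneAnnotation) -> pd.DataFrame:
    """Deterministic SNP placement shared by all phenotypes: SNPs uniform in
    gene bodies +/- 20 kb plus a fraction in intergenic gaps."""
    rng = _rng(config.seed, "genome", offset=100)
    lo, hi = config.n_snps_per_gene
    rows = []
    k = 0
    for gene in annotation.table.itertuples(index=False):
        n = int(rng.integers(lo, hi, endpoint=True))
        left = max(1, gene.start - 20_000)
        positions = rng.integers(left, gene.end + 20_000, size=n, endpoint=True)
        for p in np.sort(positions):
            rows.append((f"rs{k:06d}", gene.chrom, int(p), gene.gene_id))
            k += 1
    n_inter = int(config.intergenic_snp_fraction * len(rows))
    chroms = annotation.table["chrom"].unique()
    span = annotation.table.groupby("chrom")["end"].max()
    for _ in range(n_inter):
        c = chroms[int(rng.integers(0, len(chroms)))]
        rows.append((f"rs{k:06d}", str(c), int(rng.integers(1, span[c], endpoint=True)), ""))
        k += 1
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "source_gene"])


def simulate_gwas(
    config: SimConfig,
    phenotype: str,
    annotation: GeneAnnotation | None = None,
    causal_genes: set[str] | None = None,
) -> GwasSummary:
    """Summary statistics for one phenotype.

    Non-causal SNPs draw p ~ Uniform(0,1).  SNPs generated for causal genes
    draw a noncentral chi-square(1, lambda) statistic and report its central
    chi-square upper-tail probability, so lambda = 0 reduces exactly to the
    null.  Association is simulated directly on the summary-statistic scale
    because the pipeline consumes nothing else.
    """
    if annotation is None:
        annotation = simulate_genome(config)
    if causal_genes is None:
        pathways, causal_map = simulate_pathways(config, annotation)
        causal_genes = set()
        for pid in causal_map.get(phenotype, []):
            causal_genes |= pathways.genes(pid)
    lam = config.lam(phenotype)

    layout = _snp_layout(config, annotation)
    phenos = ["SCZ", *SMOKING_PHENOTYPES, "null", "height"]
    offset = phenos.index(phenotype) if phenotype in phenos else 10 + (hash(phenotype) % 100)
    rng = _rng(config.seed, "gwas", offset=offset)

    p = rng.uniform(0.0, 1.0, size=len(layout))
    is_causal = layout["source_gene"].isin(causal_genes).to_numpy()
    if lam > 0 and is_causal.any():
        x = rng.noncentral_chisquare(df=1, nonc=lam, size=int(is_causal.sum()))
        p[is_causal] = stats.chi2.sf(x, df=1)
    # guard the open-interval invariant
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    df = layout[["snp", "chrom", "pos"]].copy()
    df["p"] = p
    return GwasSummary(phenotype=phenotype, records=df)


def simulate_all_gwas(
    config: SimConfig,
    annotation: GeneAnnotation,
    pathways: PathwayCollection,
    causal_map: dict[str, list[str]],
) -> dict[str, GwasSummary]:
    out = {}
    for ph in ["SCZ", *SMOKING_PHENOTYPES, "null", "height"]:
        genes: set[str] = set()
        for pid in causal_map.get(ph, []):
            genes |= pathways.genes(pid)
        out[ph] = simulate_gwas(config, ph, annotation, genes)
    return out


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _logistic2(m: np.ndarray) -> np.ndarray:
    """M-value (log2 odds) -> beta in (0,1)."""
    return 1.0 / (1.0 + np.exp2(-m))


def simulate_methylation(
    config: SimConfig,
    annotation: GeneAnnotation | None = None,
    target_genes: list[str] | None = None,
    dmp_genes: list[str] | None = None,
) -> tuple[MatrixTable, MatrixTable, pd.DataFrame, pd.DataFrame, list[str]]:
    """Case/control methylation with planted differential loci.

    Latent M-values are standard normal plus a case shift ``meth_effect_delta``
    on every CpG of the planted genes, plus age and sex covariate effects;
    beta values are the logistic transform, strictly inside (0,1).

    Returns (beta matrix, M matrix, sample sheet, cpg map, planted cpg ids).
    """
    if annotation is None:
        annotation = simulate_genome(config)
    ann = annotation.table.set_index("gene_id")
    rng = _rng(config.seed, "methylation")
    if target_genes is None:
        target_genes = list(
            rng.choice(annotation.gene_ids, size=config.n_smoking_meth_genes, replace=False)
        )
    if dmp_genes is None:
        n_dmp = min(config.n_dmp_genes, len(target_genes))
        dmp_genes = list(rng.choice(target_genes, size=n_dmp, replace=False))
    missing = [g for g in dmp_genes if g not in target_genes]
    if missing:
        raise ConfigError(
            f"effect specified for gene(s) with no CpGs: {missing[:3]}"
        )

    # CpG placement inside gene bodies
    rows = []
    for g in target_genes:
        start, end, chrom = ann.loc[g, "start"], ann.loc[g, "end"], ann.loc[g, "chrom"]
        for j, pos in enumerate(np.sort(rng.integers(start, end, size=config.cpgs_per_gene,
                                                     endpoint=True))):
            rows.append((f"cg_{g}_{j}", g, chrom, int(pos)))
    cpg_map = pd.DataFrame(rows, columns=["cpg_id", "gene_id", "chrom", "pos"])

    n = config.n_cases + config.n_controls
    case = np.r_[np.ones(config.n_cases), np.zeros(config.n_controls)]
    age = rng.uniform(20, 70, size=n)
    sex = (rng.random(n) < 0.5).astype(float)
    samples = pd.DataFrame(
        {"case": case.astype(int), "age": age, "sex": sex.astype(int)},
        index=[f"S{i:03d}" for i in range(n)],
    )

    m = rng.standard_normal((len(cpg_map), n))
    m += config.age_coef * (age - 45.0) + config.sex_coef * sex
    planted = cpg_map["gene_id"].isin(dmp_genes).to_numpy()
    if config.meth_effect_delta != 0:
        m[planted] += config.meth_effect_delta * case
    dmp_cpgs = cpg_map.loc[planted, "cpg_id"].tolist() if config.meth_effect_delta != 0 else []

    m_df = pd.DataFrame(m, index=cpg_map["cpg_id"].to_numpy(), columns=samples.index)
    beta_df = pd.DataFrame(_logistic2(m), index=m_df.index, columns=m_df.columns)
    return (
        MatrixTable(values=beta_df),
        MatrixTable(values=m_df),
        samples,
        cpg_map,
        dmp_cpgs,
    )


# ---------------------------------------------------------------------------
# genotypes with planted cis effects
# ---------------------------------------------------------------------------

def simulate_genotypes_with_qtl(
    config: SimConfig,
    cpg_map: pd.DataFrame,
    target_m: MatrixTable,
) -> tuple[MatrixTable, MatrixTable, list[tuple[str, str]]]:
    """Dosage matrix with planted cis effects injected into a feature matrix.

    Dosages are Binomial(2, maf).  When ``ld_rho`` > 0 each planted SNP gets a
    partner SNP generated from a shared latent Gaussian (threshold model), so
    pairs land in strong LD.  For each planted (snp, cpg) pair the target
    M-value row gains ``qtl_slope`` x dosage.  Returns (genotypes, modified
    target, planted pairs); the input matrix is not mutated.
    """
    rng = _rng(config.seed, "genotypes")
    m = target_m.values.copy()
    # the genotyped cohort is the target-feature cohort by construction
    n = m.shape[1]

    n_pairs = min(config.n_qtl_pairs, len(cpg_map))
    pair_idx = rng.choice(len(cpg_map), size=n_pairs, replace=False)
    snp_rows, dose_rows, pairs = [], [], []
    k = 0

    def _new_snp(chrom: str, pos: int, dosage: np.ndarray, maf: float, block: int):
        nonlocal k
        sid = f"qs{k:05d}"
        snp_rows.append((sid, chrom, pos, maf, block))
        dose_rows.append(dosage)
        k += 1
        return sid

    for b, i in enumerate(pair_idx):
        cpg = cpg_map.iloc[i]
        maf = float(rng.uniform(*config.maf_range))
        pos = int(cpg["pos"] + rng.integers(-config.qtl_window, config.qtl_window,
                                            endpoint=True))
        if config.ld_rho > 0:
            # haplotype-copy LD model: each partner allele copies the tag
            # allele with probability ld_rho, else is drawn fresh at the
            # same maf, so the dosage correlation is approximately ld_rho
            h1 = (rng.random((2, n)) < maf).astype(float)
            fresh = (rng.random((2, n)) < maf).astype(float)
            copy = rng.random((2, n)) < config.ld_rho
            h2 = np.where(copy, h1, fresh)
            dosage = h1.sum(axis=0)
            d2 = h2.sum(axis=0)
            sid = _new_snp(cpg["chrom"], max(1, pos), dosage, maf, b)
            _new_snp(cpg["chrom"], max(1, pos + 500), d2, maf, b)
        else:
            dosage = rng.binomial(2, maf, size=n).astype(float)
            sid = _new_snp(cpg["chrom"], max(1, pos), dosage, maf, b)
        if config.qtl_slope != 0:
            m.loc[cpg["cpg_id"]] += config.qtl_slope * dosage
            pairs.append((sid, str(cpg["cpg_id"])))

    # null SNPs near random CpGs (cis-testable but effect-free)
    null_idx = rng.choice(len(cpg_map), size=min(config.n_null_geno_snps, len(cpg_map)),
                          replace=False)
    for i in null_idx:
        cpg = cpg_map.iloc[i]
        maf = float(rng.uniform(*config.maf_range))
        pos = int(cpg["pos"] + rng.integers(-config.qtl_window, config.qtl_window,
                                            endpoint=True))
        _new_snp(cpg["chrom"], max(1, pos), rng.binomial(2, maf, size=n).astype(float),
                 maf, -1)

    meta = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "maf", "ld_block"])
    meta = meta.set_index("snp_id")
    geno = pd.DataFrame(np.vstack(dose_rows), index=meta.index, columns=m.columns)
    return (
        MatrixTable(values=geno, row_meta=meta),
        MatrixTable(values=m),
        pairs,
    )


# ---------------------------------------------------------------------------
# expression designs
# ---------------------------------------------------------------------------

def _factor_modules(
    rng: np.random.Generator,
    module_spec,
    n_noise: int,
    n_samples: int,
    gene_pool: list[str],
) -> tuple[pd.DataFrame, dict[str, int], np.ndarray]:
    """Factor model: gene = sqrt(rho) x module latent + sqrt(1-rho) x noise,
    so within-module correlation is rho.  Label 0 = unassigned noise genes."""
    n_mod_genes = sum(s for s, _ in module_spec)
    total = n_mod_genes + n_noise
    if total > len(gene_pool):
        raise ConfigError("gene pool too small for module spec")
    genes = gene_pool[:total]
    values = np.empty((total, n_samples))
    assignment: dict[str, int] = {}
    latents = np.empty((len(module_spec), n_samples))
    row = 0
    for mi, (size, rho) in enumerate(module_spec, start=1):
        f = rng.standard_normal(n_samples)
        latents[mi - 1] = f
        eps = rng.standard_normal((size, n_samples))
        values[row:row + size] = np.sqrt(rho) * f + np.sqrt(1 - rho) * eps
        for g in genes[row:row + size]:
            assignment[g] = mi
        row += size
    values[row:] = rng.standard_normal((n_noise, n_samples))
    for g in genes[row:]:
        assignment[g] = 0
    df = pd.DataFrame(values, index=genes, columns=[f"E{i:03d}" for i in range(n_samples)])
    return df, assignment, latents


def simulate_expression_brain(
    config: SimConfig, gene_pool: list[str]
) -> tuple[MatrixTable, dict[str, int], list[int], list[int]]:
    """Region x developmental-stage expression with planted co-expression
    modules; module 1 carries a regional fold change >= ``regional_fold``
    between the first region and the rest, module 2 a temporal fold change
    across stages.  Values are on the log2 scale."""
    rng = _rng(config.seed, "expr_brain")
    cells = [(r, s) for r in config.regions for s in config.stages]
    n_samples = len(cells) * config.reps_per_cell
    df, assignment, _ = _factor_modules(
        rng, config.module_spec, config.n_brain_noise_genes, n_samples, gene_pool
    )
    meta = pd.DataFrame(
        [(r, s) for (r, s) in cells for _ in range(config.reps_per_cell)],
        columns=["region", "stage"],
        index=df.columns,
    )
    regional_mods, temporal_mods = [], []
    if len(config.module_spec) >= 1 and config.regional_fold > 1:
        shift = np.log2(config.regional_fold)
        mask = (meta["region"] == config.regions[0]).to_numpy()
        genes1 = [g for g, m in assignment.items() if m == 1]
        df.loc[genes1, df.columns[mask]] += shift
        regional_mods.append(1)
    if len(config.module_spec) >= 2 and config.temporal_fold > 1:
        shift = np.log2(config.temporal_fold)
        stage_rank = meta["stage"].map({s: i for i, s in enumerate(config.stages)})
        frac = (stage_rank / max(1, len(config.stages) - 1)).to_numpy()
        genes2 = [g for g, m in assignment.items() if m == 2]
        df.loc[genes2] += shift * frac
        temporal_mods.append(2)
    return MatrixTable(values=df, col_meta=meta), assignment, regional_mods, temporal_mods


def simulate_expression_groups(
    config: SimConfig, gene_pool: list[str], de_genes: list[str]
) -> MatrixTable:
    """Four-group design (disease x smoking status); planted genes get a
    ``de_effect`` shift in the disease-smoker group."""
    rng = _rng(config.seed, "expr_groups")
    groups = ["SCZ_smoker", "SCZ_nonsmoker", "control_smoker", "control_nonsmoker"]
    labels = [g for g in groups for _ in range(config.n_per_group)]
    genes = sorted(set(gene_pool) | set(de_genes))
    values = rng.standard_normal((len(genes), len(labels)))
    df = pd.DataFrame(values, index=genes,
                      columns=[f"O{i:02d}" for i in range(len(labels))])
    mask = np.array([lab == "SCZ_smoker" for lab in labels])
    df.loc[de_genes, df.columns[mask]] += config.de_effect
    meta = pd.DataFrame({"group": labels}, index=df.columns)
    return MatrixTable(values=df, col_meta=meta)


def simulate_expression_dose(
    config: SimConfig,
    drug: str,
    gene_pool: list[str],
    candidate_genes: list[str],
    drug_offset: int = 0,
) -> tuple[MatrixTable, list[str]]:
    """Dose series for one drug.  Responsive genes gain a monotone mean shift
    of ``dose_slope`` per dose rank (random sign per gene); candidates are
    responsive at a higher rate than background, mirroring a drug-prone
    candidate set."""
    rng = _rng(config.seed, "expr_dose", offset=drug_offset)
    doses = config.drug_doses[drug]
    labels = [d for d in doses for _ in range(config.n_per_dose)]
    genes = sorted(set(gene_pool) | set(candidate_genes))
    values = rng.standard_normal((len(genes), len(labels)))
    df = pd.DataFrame(values, index=genes,
                      columns=[f"D{drug[:2]}{i:02d}" for i in range(len(labels))])
    rank = np.array([list(doses).index(d) for d in labels], dtype=float)
    responsive = []
    for g in genes:
        frac = (config.candidate_responsive_frac if g in set(candidate_genes)
                else config.background_responsive_frac)
        if rng.random() < frac:
            sign = -1.0 if rng.random() < 0.5 else 1.0
            df.loc[g] += sign * config.dose_slope * rank
            responsive.append(g)
    meta = pd.DataFrame({"dose": labels}, index=df.columns)
    return MatrixTable(values=df, col_meta=meta), responsive


# ---------------------------------------------------------------------------
# network & literature
# ---------------------------------------------------------------------------

def simulate_ppi(
    config: SimConfig, nodes: list[str], candidate_genes: list[str]
) -> pd.DataFrame:
    """Erdos-Renyi background plus dense wiring among candidates."""
    rng = _rng(config.seed, "ppi")
    nodes = list(nodes)[: config.ppi_n_nodes]
    node_set = sorted(set(nodes) | set(candidate_genes))
    edges = set()
    arr = np.array(node_set)
    n = len(arr)
    # background: sample ER edges by count for speed
    n_bg = rng.binomial(n * (n - 1) // 2, config.ppi_background_p)
    while len(edges) < n_bg:
        i, j = rng.integers(0, n, size=2)
        if i != j:
            a, b = sorted((arr[i], arr[j]))
            edges.add((a, b))
    cand = sorted(set(candidate_genes))
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            if rng.random() < config.ppi_candidate_p:
                edges.add((cand[i], cand[j]))
    df = pd.DataFrame(sorted(edges), columns=["node_a", "node_b"])
    return df


# ---------------------------------------------------------------------------
# full corpus
# ---------------------------------------------------------------------------

def simulate_corpus(config: SimConfig | None = None) -> SimCorpus:
    """Build the complete synthetic study: genome, pathways, seven GWAS,
    methylation + genotypes with planted cis effects, three expression
    designs, the interaction network and literature flags, wired together so
    the convergence construction has a well-defined planted answer."""
    config = config or SimConfig()
    annotation = simulate_genome(config)
    pathways, causal_map = simulate_pathways(config, annotation)
    causal_genes = {
        ph: sorted(set().union(*[pathways.genes(p) for p in pids]) if pids else set())
        for ph, pids in causal_map.items()
    }
    gwas = simulate_all_gwas(config, annotation, pathways, causal_map)

    # module genes drawn from the shared causal pathways first (convergence
    # design: co-expression modules overlap the GWAS signal), then fill
    rng = _rng(config.seed, "methylation", offset=50)
    shared_genes = causal_genes["SCZ"]
    pool = list(shared_genes) + [g for g in annotation.gene_ids if g not in set(shared_genes)]
    brain, module_assignment, regional_mods, temporal_mods = simulate_expression_brain(
        config, pool
    )
    module_genes = [g for g, m in module_assignment.items() if m > 0]

    # smoking-associated methylation genes: drawn mostly from module genes
    n_from_modules = min(len(module_genes), int(0.8 * config.n_smoking_meth_genes))
    smoking_meth = list(rng.choice(module_genes, size=n_from_modules, replace=False))
    others = [g for g in annotation.gene_ids if g not in set(smoking_meth)]
    smoking_meth += list(
        rng.choice(others, size=config.n_smoking_meth_genes - n_from_modules, replace=False)
    )
    beta, m_latent, samples, cpg_map, dmp_cpgs = simulate_methylation(
        config, annotation, target_genes=smoking_meth
    )
    dmp_genes = sorted(set(cpg_map.set_index("cpg_id").loc[dmp_cpgs, "gene_id"]))

    genotypes, m_latent, qtl_pairs = simulate_genotypes_with_qtl(config, cpg_map, m_latent)
    beta = MatrixTable(
        values=pd.DataFrame(
            _logistic2(m_latent.values.to_numpy()),
            index=m_latent.values.index,
            columns=m_latent.values.columns,
        )
    )

    # external curated support counts per methylation gene (input column);
    # skewed low so the >=2-evidence filter keeps roughly a quarter
    ev_rng = _rng(config.seed, "literature", offset=1)
    meth_evidence = pd.DataFrame(
        {
            "gene_id": sorted(smoking_meth),
            "n_evidence": ev_rng.choice(
                np.arange(1, len(config.evidence_probs) + 1),
                size=len(smoking_meth),
                p=config.evidence_probs,
            ),
        }
    )
    well_supported = set(
        meth_evidence.loc[meth_evidence["n_evidence"] >= 2, "gene_id"]
    )

    # planted candidate set: module genes on the smoking panel with >=2
    # pieces of curated support that are differentially methylated in cases
    candidates = sorted(
        set(module_genes) & set(smoking_meth) & well_supported & set(dmp_genes)
    )

    de_genes = list(rng.choice(candidates, size=min(config.n_de_genes, len(candidates)),
                               replace=False))
    cc_pool = list(rng.choice(annotation.gene_ids, size=config.n_cc_background_genes,
                              replace=False))
    case_control = simulate_expression_groups(config, cc_pool, de_genes)

    expression = {"brain": brain, "case_control": case_control}
    drug_responsive = {}
    dose_pool = list(rng.choice(annotation.gene_ids, size=config.n_dose_background_genes,
                                replace=False))
    for di, drug in enumerate(config.drug_doses):
        mat, responsive = simulate_expression_dose(config, drug, dose_pool, candidates, di)
        expression[f"dose:{drug}"] = mat
        drug_responsive[drug] = responsive

    ppi = simulate_ppi(config, annotation.gene_ids, candidates)
    lit_rng = _rng(config.seed, "literature")
    lit_flags = pd.DataFrame(
        {
            "gene_id": candidates,
            "literature": lit_rng.random(len(candidates)) < config.literature_frac,
        }
    )

    truth = GroundTruth(
        causal_pathways=causal_map,
        causal_genes=causal_genes,
        smoking_meth_genes=sorted(smoking_meth),
        dmp_genes=dmp_genes,
        dmp_cpgs=dmp_cpgs,
        qtl_pairs=qtl_pairs,
        module_assignment=module_assignment,
        de_genes=sorted(de_genes),
        drug_responsive_genes={d: sorted(v) for d, v in drug_responsive.items()},
        regional_modules=regional_mods,
        temporal_modules=temporal_mods,
        candidate_genes=candidates,
    )
    return SimCorpus(
        config=config,
        annotation=annotation,
        pathways=pathways,
        gwas=gwas,
        methylation=beta,
        meth_m=m_latent,
        meth_samples=samples,
        cpg_map=cpg_map,
        genotypes=genotypes,
        expression=expression,
        ppi_edges=ppi,
        literature=lit_flags,
        meth_evidence=meth_evidence,
        truth=truth,
    )
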