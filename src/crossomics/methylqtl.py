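"""Differential methylation, convergence with exact binomial consistency
tests, LD expansion, and cis-meQTL/eQTL regression.

Methylation is analyzed on the M-value scale, log2(beta / (1 - beta)):
beta proportions are heteroskedastic near the boundaries, and the log-odds
transform stabilizes the variance for ordinary least squares.  The same
per-pair additive regression engine serves methylation and expression
features; "feature" below is either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import MatrixTable, bonferroni_threshold
from .enrich import bh_qvalues
from .errors import ConfigError, DegenerateInputError


def mvalue(beta, eps: float = 1e-6) -> np.ndarray:
    """M-value transform log2(b / (1-b)) with b clamped to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


# ---------------------------------------------------------------------------
# differential methylation
# ---------------------------------------------------------------------------

@dataclass
class DmpResult:
    """Per-CpG case-effect tests.

    ``rows``: cpg_id -> (estimate, t, p, significant); untestable
    (zero-variance) CpGs carry NaN statistics, significant=False, and are
    excluded from ``n_tests``; threshold = alpha / n_tests.
    """

    rows: pd.DataFrame
    n_tests: int
    threshold: float
    alpha: float = 0.05


def dmp_test(
    m: MatrixTable,
    case_labels,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DmpResult:
    """Mass-univariate OLS of M-value on a case indicator plus covariates.

    p is the two-sided t probability of the case coefficient with
    n - p_params residual degrees of freedom.  With no covariates this is
    algebraically the pooled-variance two-sample t-test.
    """
    y = m.values.to_numpy(dtype=float)  # features x samples
    case = np.asarray(case_labels, dtype=float)
    n = y.shape[1]
    if case.shape[0] != n:
        raise ConfigError("case_labels length does not match sample count")
    if (case == 1).sum() < 2 or (case == 0).sum() < 2:
        raise ConfigError("need >= 2 samples per group")
    cols = [np.ones(n), case]
    if covariates is not None:
        cov = covariates.to_numpy(dtype=float)
        cols.extend(cov.T)
    x = np.column_stack(cols)
    p_params = x.shape[1]
    if np.linalg.matrix_rank(x) < p_params:
        raise ConfigError("design matrix (case + covariates) is rank deficient")

    # tolerance absorbs float accumulation noise in genuinely constant rows
    testable = y.std(axis=1) > 1e-10 * (1.0 + np.abs(y).max(axis=1))
    yt = y[testable]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ yt.T  # p_params x features
    resid = yt.T - x @ beta
    dof = n - p_params
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)

    n_tests = int(testable.sum())
    if n_tests == 0:
        raise DegenerateInputError("no testable CpG (all rows constant)")
    thr = bonferroni_threshold(alpha, n_tests)
    rows = pd.DataFrame(
        index=m.values.index,
        data={"estimate": np.nan, "t": np.nan, "p": np.nan, "significant": False},
    )
    rows.loc[rows.index[testable], ["estimate", "t", "p"]] = np.column_stack(
        [beta[1], t, pvals]
    )
    rows["significant"] = (rows["p"] < thr).astype(bool)  # NaN compares False
    return DmpResult(rows=rows, n_tests=n_tests, threshold=thr, alpha=alpha)


# ---------------------------------------------------------------------------
# exact binomial consistency
# ---------------------------------------------------------------------------

def binomial_consistency(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value by the minimum-likelihood rule:
    sum of P(X = i) over all i with P(X = i) <= P(X = k), X ~ Bin(n, p0).
    For p0 = 0.5 this equals the doubled tail (capped at 1)."""
    if k > n:
        raise ValueError("k must not exceed n")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(stats.binomtest(int(k), int(n), p=p0).pvalue)


@dataclass
class ConvergenceResult:
    """Staged convergence of co-expression module genes with smoking- and
    disease-associated methylation."""

    stage1: set[str]  # module genes that are smoking-methylation genes
    stage2: set[str]  # stage1 with >= min_evidence supporting entries
    stage3_of_stage1: set[str]  # stage1 genes with a Bonferroni-significant CpG
    stage3_of_stage2: set[str]
    binomial_p_stage1: float | None
    binomial_p_stage2: float | None
    status: str = "ok"  # "skipped" when stage1 is empty

    @property
    def counts(self) -> dict[str, int]:
        return {
            "stage1": len(self.stage1),
            "stage2": len(self.stage2),
            "stage3_of_stage1": len(self.stage3_of_stage1),
            "stage3_of_stage2": len(self.stage3_of_stage2),
        }


def genes_with_significant_cpg(dmp: DmpResult, cpg_map: pd.DataFrame) -> set[str]:
    """Genes harboring at least one Bonferroni-significant CpG."""
    sig_cpgs = dmp.rows.index[dmp.rows["significant"]]
    cm = cpg_map.set_index("cpg_id")
    return set(cm.loc[cm.index.intersection(sig_cpgs), "gene_id"])


def convergence_filter(
    module_genes,
    smoking_meth_genes,
    evidence_counts: pd.Series,
    dmp: DmpResult,
    cpg_map: pd.DataFrame,
    min_evidence: int = 2,
) -> ConvergenceResult:
    """Staged intersection of module genes with methylation evidence.

    stage1 = modules ∩ smoking methylation; stage2 = stage1 with evidence
    count >= ``min_evidence`` (the evidence-count column is an input, not
    re-derived); stage3 = members harboring a significant CpG.  The two
    exact binomial tests ask whether disease-methylation hits among stage1
    (resp. stage2) exceed a coin flip.
    """
    stage1 = set(module_genes) & set(smoking_meth_genes)
    if not stage1:
        return ConvergenceResult(set(), set(), set(), set(), None, None,
                                 status="skipped")
    ev = evidence_counts.reindex(sorted(stage1)).fillna(0)
    stage2 = set(ev.index[ev >= min_evidence])
    sig_genes = genes_with_significant_cpg(dmp, cpg_map)
    s3_1 = stage1 & sig_genes
    s3_2 = stage2 & sig_genes
    p1 = binomial_consistency(len(s3_1), len(stage1))
    p2 = binomial_consistency(len(s3_2), len(stage2)) if stage2 else None
    return ConvergenceResult(stage1, stage2, s3_1, s3_2, p1, p2)


# ---------------------------------------------------------------------------
# LD expansion and cis pairing
# ---------------------------------------------------------------------------

def ld_expand(
    tags,
    genotypes: MatrixTable,
    r2_cut: float = 0.5,
    window: int = 1_000_000,
) -> set[str]:
    """Expand tag SNPs to all SNPs in strong LD (r^2 >= r2_cut).

    r^2 is the squared Pearson correlation of dosage vectors; only SNPs on
    the tag's chromosome within ``window`` bp are considered.  Tags are
    always included.
    """
    meta = genotypes.row_meta
    if meta is None or not {"chrom", "pos"} <= set(meta.columns):
        raise ConfigError("genotypes need row_meta with chrom and pos for ld_expand")
    dose = genotypes.values
    out = set()
    for tag in tags:
        if tag not in dose.index:
            raise ConfigError(f"tag SNP {tag!r} not in genotype matrix")
        out.add(tag)
        chrom, pos = meta.loc[tag, "chrom"], meta.loc[tag, "pos"]
        near = meta[(meta["chrom"] == chrom) & ((meta["pos"] - pos).abs() <= window)]
        g = dose.loc[tag].to_numpy()
        if g.std() == 0:
            continue
        cand = dose.loc[near.index.difference([tag])]
        sd = cand.std(axis=1, ddof=0)
        ok = sd > 0
        if not ok.any():
            continue
        c = cand[ok]
        r = ((c - c.mean(axis=1).to_numpy()[:, None]) @ (g - g.mean())) / (
            len(g) * c.std(axis=1, ddof=0) * g.std()
        )
        out |= set(c.index[(r ** 2) >= r2_cut])
    return out


def cis_pairs(
    snp_meta: pd.DataFrame,
    feature_meta: pd.DataFrame,
    window: int = 20_000,
) -> pd.DataFrame:
    """All (snp, feature) pairs on the same chromosome with |Δpos| <= window
    (boundary inclusive).  ``snp_meta``/``feature_meta`` need id index or an
    id column plus chrom and pos."""
    def _norm(df, id_col):
        if id_col in df.columns:
            df = df.set_index(id_col)
        return df
    snp_meta = _norm(snp_meta, "snp_id")
    feature_meta = _norm(feature_meta, "feature_id")
    rows = []
    for chrom, snps in snp_meta.groupby("chrom"):
        feats = feature_meta[feature_meta["chrom"] == chrom]
        if feats.empty:
            continue
        dpos = np.abs(snps["pos"].to_numpy()[:, None] - feats["pos"].to_numpy()[None, :])
        si, fi = np.nonzero(dpos <= window)
        for i, j in zip(si, fi):
            rows.append((snps.index[i], feats.index[j]))
    return pd.DataFrame(rows, columns=["snp_id", "feature_id"])


# ---------------------------------------------------------------------------
# cis-QTL regression
# ---------------------------------------------------------------------------

@dataclass
class QtlPairs:
    """Per-pair additive-model regression results.

    ``rows``: (snp_id, feature_id) multi-indexed frame with beta, t, p, fdr,
    significant; ``skipped`` lists monomorphic SNP pairs left untested.
    """

    rows: pd.DataFrame
    window: int
    fdr_cut: float
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.rows[self.rows["significant"]]


def _residualize(y: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Project out covariates (with intercept) from each row of y."""
    x = np.column_stack([np.ones(y.shape[-1]), cov])
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return y - (x @ beta).T


def qtl_regression(
    genotypes: MatrixTable,
    features: MatrixTable,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr_cut: float = 0.01,
    window: int = 20_000,
) -> QtlPairs:
    """Additive-model OLS of each feature on its paired SNP dosage.

    Dosage enters linearly (0/1/2 or fractional), so the slope is the
    per-allele effect.  Covariates, when given, are projected out of both
    sides first (Frisch-Waugh) with degrees of freedom adjusted accordingly.
    BH FDR is computed across all tested pairs; monomorphic SNPs are
    skipped and reported.
    """
    samples = features.values.columns.intersection(genotypes.values.columns)
    if len(samples) < 4:
        raise ConfigError("need >= 4 shared samples")
    g_all = genotypes.values[samples]
    y_all = features.values[samples]
    n = len(samples)
    n_cov = 0
    if covariates is not None:
        cov = covariates.loc[samples].to_numpy(dtype=float)
        n_cov = cov.shape[1]

    tested, skipped = [], []
    for snp, feat in pairs.itertuples(index=False):
        if snp not in g_all.index or feat not in y_all.index:
            skipped.append((snp, feat))
            continue
        if g_all.loc[snp].nunique() < 2:
            skipped.append((snp, feat))
            continue
        tested.append((snp, feat))
    if not tested:
        empty = pd.DataFrame(columns=["beta", "t", "p", "fdr", "significant"])
        return QtlPairs(rows=empty, window=window, fdr_cut=fdr_cut, skipped=skipped)

    snps = [s for s, _ in tested]
    feats = [f for _, f in tested]
    g = g_all.loc[snps].to_numpy(dtype=float)
    y = y_all.loc[feats].to_numpy(dtype=float)
    if covariates is not None:
        g = _residualize(g, cov)
        y = _residualize(y, cov)
    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (gc ** 2).sum(axis=1)
    sxy = (gc * yc).sum(axis=1)
    syy = (yc ** 2).sum(axis=1)
    beta = sxy / sxx
    dof = n - 2 - n_cov
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / dof / sxx)
    with np.errstate(divide="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    fdr = bh_qvalues(p)
    rows = pd.DataFrame(
        {"beta": beta, "t": t, "p": p, "fdr": fdr, "significant": fdr < fdr_cut},
        index=pd.MultiIndex.from_tuples(tested, names=["snp_id", "feature_id"]),
    )
    return QtlPairs(rows=rows, window=window, fdr_cut=fdr_cut, skipped=skipped)
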