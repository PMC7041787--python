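"""SNP-to-gene assignment and per-gene association scores from GWAS
summary statistics.

Each SNP is assigned to at most one gene: any gene whose body extended by
the window (default 20 kb, boundaries inclusive) covers the SNP is eligible,
and ties are broken by distance to the gene body (zero inside the body),
then lexicographically by gene id.  The per-gene score is the best (minimum)
assigned SNP p-value on the -log10 scale, with a Sidak adjustment
1 - (1 - p)^n for the number of assigned SNPs.  This best-SNP statistic
assumes independent SNPs; it deliberately ignores LD, which a multi-SNP
gene model would absorb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import GeneAnnotation, GwasSummary, neglog10
from .errors import ConsistencyError


@dataclass
class GeneScoreTable:
    """Per-gene best-SNP scores for one phenotype.

    ``rows`` is indexed by gene_id with columns
    best_snp, best_p, n_snps, score (= -log10 best_p), adj_p (Sidak).
    Genes with no assigned SNP are absent, never zero-filled.
    """

    phenotype: str
    rows: pd.DataFrame

    @property
    def scores(self) -> pd.Series:
        return self.rows["score"]


def assign_snps_to_genes(
    gwas: GwasSummary,
    annotation: GeneAnnotation,
    window: int = 20_000,
) -> pd.Series:
    """Map snp_id -> gene_id for SNPs within ``window`` bp of a gene body.

    A SNP at exactly start - window or end + window is assigned (inclusive
    boundary).  Unmapped SNPs are omitted from the result.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    ann = annotation.table
    out_snps: list[str] = []
    out_genes: list[str] = []
    for chrom, snps in gwas.records.groupby("chrom", sort=False):
        # genes pre-sorted by id so argmin's first-minimum rule breaks
        # distance ties toward the lexicographically smaller gene_id
        genes = ann[ann["chrom"] == chrom].sort_values("gene_id")
        if genes.empty:
            continue
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        gids = genes["gene_id"].to_numpy()
        pos = snps["pos"].to_numpy()
        # distance to gene body: 0 inside, else gap size (broadcast SNPs x genes)
        dist = np.maximum.reduce(
            [starts[None, :] - pos[:, None], pos[:, None] - ends[None, :],
             np.zeros((len(pos), len(gids)), dtype=np.int64)]
        )
        best = np.argmin(dist, axis=1)
        best_dist = dist[np.arange(len(pos)), best]
        keep = best_dist <= window
        out_snps.extend(snps["snp"].to_numpy()[keep])
        out_genes.extend(gids[best[keep]])
    return pd.Series(out_genes, index=pd.Index(out_snps, name="snp"), name="gene_id")


def gene_scores(gwas: GwasSummary, assignment: pd.Series,
                annotation: GeneAnnotation | None = None) -> GeneScoreTable:
    """Best-SNP score per gene with a Sidak-adjusted p-value.

    adj_p = 1 - (1 - best_p)^n_snps, the exact null distribution of the
    minimum of n independent uniform p-values.
    """
    if annotation is not None:
        unknown = set(assignment.unique()) - set(annotation.gene_ids)
        if unknown:
            raise ConsistencyError(
                f"assigned gene(s) missing from annotation: {sorted(unknown)[:3]}"
            )
    df = gwas.records.set_index("snp").join(assignment.rename("gene_id"), how="inner")
    if df.empty:
        return GeneScoreTable(
            phenotype=gwas.phenotype,
            rows=pd.DataFrame(
                columns=["best_snp", "best_p", "n_snps", "score", "adj_p"]
            ),
        )
    df = df.reset_index()
    idx = df.groupby("gene_id")["p"].idxmin()
    best = df.loc[idx].set_index("gene_id")
    n_snps = df.groupby("gene_id").size()
    rows = pd.DataFrame(
        {
            "best_snp": best["snp"],
            "best_p": best["p"],
            "n_snps": n_snps,
        }
    )
    rows["score"] = neglog10(rows["best_p"])
    # log1p-based form keeps precision for tiny p
    rows["adj_p"] = -np.expm1(rows["n_snps"].to_numpy()
                              * np.log1p(-rows["best_p"].to_numpy()))
    rows = rows.sort_index()
    return GeneScoreTable(phenotype=gwas.phenotype, rows=rows)


def significant_genes(table: GeneScoreTable, alpha: float = 0.05) -> list[str]:
    """Bonferroni-corrected gene call: adj_p below alpha / number of genes
    tested."""
    n = len(table.rows)
    if n == 0:
        return []
    thr = alpha / n
    return sorted(table.rows.index[table.rows["adj_p"] < thr])
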