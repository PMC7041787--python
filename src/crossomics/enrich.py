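"""Gene-set enrichment from gene scores, FDR control, cross-phenotype
shared-pathway detection and phenotype similarity.

The set statistic is a one-sample Z of the pathway's mean gene score
against the population of all scored genes:

    z = (mean_set - mean_all) / (sd_all / sqrt(m)),   m = scored set size

with a one-sided (upper-tail) normal p-value.  Genes in a pathway but
absent from the score table are ignored, not imputed.  The false-discovery
rate is Benjamini-Hochberg step-up throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import PathwayCollection
from .errors import DegenerateInputError
from .genescore import GeneScoreTable


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment for one phenotype: columns z, p, q,
    n_genes_scored (indexed by pathway_id)."""

    phenotype: str
    rows: pd.DataFrame


def enrichment_z(scores: pd.Series, pathway_genes) -> tuple[float, float]:
    """One-sample Z of set-mean score against the scored-gene population.

    ``scores`` is the full gene -> score series; only pathway genes present
    in it contribute.  Raises on zero overall dispersion or an unscored set.
    """
    scores = pd.Series(scores).astype(float)
    sd = scores.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError("overall score standard deviation is zero")
    members = scores.loc[scores.index.intersection(list(pathway_genes))]
    m = len(members)
    if m == 0:
        raise DegenerateInputError("no pathway gene has a score")
    z = (members.mean() - scores.mean()) / (sd / np.sqrt(m))
    return float(z), float(stats.norm.sf(z))


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_phenotype(
    scores: GeneScoreTable, pathways: PathwayCollection
) -> EnrichmentResult:
    """Z, p and BH q for every pathway with at least one scored gene."""
    s = scores.scores
    rows = {}
    for pid, pw in pathways.entries.items():
        members = s.index.intersection(list(pw.genes))
        if len(members) == 0:
            continue
        z, p = enrichment_z(s, pw.genes)
        rows[pid] = (z, p, len(members))
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["z", "p", "n_genes_scored"]
    )
    df["q"] = bh_qvalues(df["p"].to_numpy()) if len(df) else []
    return EnrichmentResult(phenotype=scores.phenotype,
                           rows=df[["z", "p", "q", "n_genes_scored"]])


def shared_pathways(
    results: list[EnrichmentResult],
    anchor: str,
    mode: str = "any",
    q_cut: float = 0.1,
) -> set[str]:
    """Pathways significant (q < q_cut) in the anchor phenotype and in at
    least one (``mode='any'``) or every (``mode='all'``) other phenotype."""
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    by_name = {r.phenotype: r for r in results}
    if anchor not in by_name:
        raise ValueError(f"anchor phenotype {anchor!r} not among results")
    sig = {
        name: set(r.rows.index[r.rows["q"] < q_cut]) for name, r in by_name.items()
    }
    others = [s for name, s in sig.items() if name != anchor]
    if not others:
        return set()
    combine = set.union if mode == "any" else set.intersection
    return sig[anchor] & combine(*others)


def z_matrix(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Pathways x phenotypes matrix of enrichment Z scores (inner join on
    pathways present in all phenotypes)."""
    cols = {r.phenotype: r.rows["z"] for r in results}
    return pd.DataFrame(cols).dropna()


def phenotype_similarity(zmat: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between phenotypes over their pathway Z profiles."""
    return zmat.corr(method="pearson")
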