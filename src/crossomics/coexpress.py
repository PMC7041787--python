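"""Weighted co-expression module detection (topological overlap),
hub-gene identification and region/stage module profiles.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the
soft power beta chosen by the scale-free fit criterion.  Topological
overlap blends direct adjacency with shared neighbours:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

and modules are average-linkage clusters of 1 - TOM below a static cut
height (a deliberate simplification of dynamic tree cutting; module counts
are therefore not comparable to pipelines that use it).  Each module is
summarized by its eigengene, the first principal component of the module's
standardized expression, oriented so the mean gene-eigengene correlation
is non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class CoexpressionModules:
    """gene -> module label (0 = unassigned), per-module eigengenes
    (samples x modules, unit norm), per-gene intramodular connectivity
    kWithin, and the soft power used."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    k_within: pd.Series
    beta: int

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta with zero diagonal (genes x genes)."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(expr.to_numpy())
    corr = np.nan_to_num(corr, nan=0.0)
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(a: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log-log regression of the connectivity
    distribution (the scale-free topology criterion)."""
    k = a.to_numpy().sum(axis=1)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        log_k.append(np.log10(k[sel].mean()))
        log_p.append(np.log10(sel.mean() + 1e-12))
    if len(log_k) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(log_k, log_p, 1)
    pred = np.polyval([slope, intercept], log_k)
    ss_res = float(((np.array(log_p) - pred) ** 2).sum())
    ss_tot = float(((np.array(log_p) - np.mean(log_p)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2, float(slope)


DEFAULT_UNSIGNED_POWER = 6  # conventional default for unsigned networks


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidates=range(1, 21),
    r2_target: float = 0.8,
) -> int:
    """Smallest power with scale-free fit R^2 >= target and negative slope.

    A qualifying power must also keep median connectivity >= 1: large
    powers drive most adjacencies toward zero, and the steeply decreasing
    connectivity histogram of an essentially empty network mimics a power
    law.  A network in which half the genes are disconnected is not a
    usable co-expression network regardless of its histogram.

    Block-structured data (a few tight modules over a noise background) is
    not scale-free and may never reach the target; the fallback is then the
    conventional default power for unsigned networks (6), with a warning.
    Chasing the argmax-R^2 power instead would push beta high enough to
    erase within-module adjacency altogether.
    """
    for beta in candidates:
        a = adjacency(expr, beta)
        r2, slope = scale_free_fit(a)
        median_k = float(np.median(a.to_numpy().sum(axis=1)))
        if slope < 0 and r2 >= r2_target and median_k >= 1.0:
            return int(beta)
    cand = [int(b) for b in candidates]
    fallback = DEFAULT_UNSIGNED_POWER if DEFAULT_UNSIGNED_POWER in cand else cand[0]
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_target}; "
        f"falling back to the default unsigned power beta={fallback}",
        stacklevel=2,
    )
    return fallback


def tom_similarity(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned network; TOM_ii = 1 and
    TOM in [0,1] elementwise."""
    a = adjacency(expr, beta).to_numpy()
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def _eigengene(expr_block: pd.DataFrame) -> np.ndarray:
    """First PC of standardized module expression over samples, unit norm,
    sign so the mean gene-eigengene correlation is >= 0."""
    x = expr_block.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    if np.corrcoef(np.vstack([e, z]))[0, 1:].mean() < 0:
        e = -e
    return e / np.linalg.norm(e)


def detect_modules(
    expr: pd.DataFrame,
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.9,
    beta: int = 6,
) -> CoexpressionModules:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters below ``min_module_size`` become label 0 (unassigned).  Modules
    are numbered 1..k by decreasing size, ties by first member index.
    """
    d = 1.0 - tom.to_numpy()
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    genes = tom.index
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    # order kept clusters by (size desc, first member index)
    first_member = {lab: int(np.argmax(raw == lab)) for lab in keep}
    ordered = sorted(keep, key=lambda lab: (-sizes[lab], first_member[lab]))
    relabel = {lab: i + 1 for i, lab in enumerate(ordered)}
    labels = pd.Series([relabel.get(lab, 0) for lab in raw], index=genes)

    a = adjacency(expr, beta)
    k_within = pd.Series(0.0, index=genes)
    eig = {}
    for mod in sorted(relabel.values()):
        members = labels.index[labels == mod]
        k_within[members] = a.loc[members, members].sum(axis=1)
        eig[mod] = _eigengene(expr.loc[members])
    eigengenes = pd.DataFrame(eig, index=expr.columns)
    return CoexpressionModules(labels=labels, eigengenes=eigengenes,
                               k_within=k_within, beta=beta)


def hub_genes(
    modules: CoexpressionModules, top_n: int = 10
) -> dict[int, list[str]]:
    """Top genes per module by intramodular connectivity kWithin
    (ties broken by gene id)."""
    out = {}
    for mod in modules.module_ids:
        members = modules.labels.index[modules.labels == mod]
        ranked = sorted(members, key=lambda g: (-modules.k_within[g], g))
        out[mod] = ranked[:top_n]
    return out


def regional_profile(
    expr: pd.DataFrame,
    modules: CoexpressionModules,
    sample_meta: pd.DataFrame,
    fold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-centered module expression per (region, stage) cell and
    fold-change flags.

    Expression is assumed log2 in the input; a module is flagged regional
    (temporal) when the spread of its region (stage) means reaches
    ``fold`` on the linear scale, i.e. log2 spread >= log2(fold).
    """
    need = {"region", "stage"}
    if not need <= set(sample_meta.columns):
        raise ValueError("sample_meta needs region and stage columns")
    log_fold = np.log2(fold)
    profiles, flags = [], []
    for mod in modules.module_ids:
        members = modules.labels.index[modules.labels == mod]
        mean_per_sample = expr.loc[members].mean(axis=0)
        grand = mean_per_sample.mean()
        cell = mean_per_sample.groupby(
            [sample_meta["region"], sample_meta["stage"]]
        ).mean() - grand
        region_means = mean_per_sample.groupby(sample_meta["region"]).mean()
        stage_means = mean_per_sample.groupby(sample_meta["stage"]).mean()
        flags.append(
            {
                "module": mod,
                "regional_2fold": bool(region_means.max() - region_means.min()
                                       >= log_fold),
                "temporal_2fold": bool(stage_means.max() - stage_means.min()
                                       >= log_fold),
            }
        )
        prof = cell.rename("value").reset_index()
        prof.insert(0, "module", mod)
        profiles.append(prof)
    profile_df = (pd.concat(profiles, ignore_index=True) if profiles
                  else pd.DataFrame(columns=["module", "region", "stage", "value"]))
    return profile_df, pd.DataFrame(flags)
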