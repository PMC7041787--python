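"""Pathway-to-pathway distance from shared genes, classical (Torgerson)
multidimensional scaling and agglomerative clustering into k groups.

The distance is Jaccard on gene sets, 1 - |A n B| / |A u B|, so identical
pathways embed at the same point and disjoint pathways at distance 1.
Classical MDS double-centers the squared distance matrix,
B = -1/2 J D^2 J, and takes coordinates from the top positive eigenpairs;
sklearn's MDS is the SMACOF stress majorizer, not this eigendecomposition,
which is why the embedding is implemented directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataio import PathwayCollection
from .errors import DegenerateInputError


@dataclass
class PathwayEmbedding:
    pathway_ids: list[str]
    distances: np.ndarray  # symmetric, zero diagonal, entries in [0,1]
    coordinates: np.ndarray  # pathways x dims
    cluster_labels: np.ndarray  # 1..k, numbered by first member index


def pathway_distance(a, b) -> float:
    """Jaccard distance between two gene sets; 0 for two empty sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def distance_matrix(pathways: PathwayCollection, ids=None) -> tuple[list[str], np.ndarray]:
    ids = list(ids) if ids is not None else list(pathways.entries)
    n = len(ids)
    d = np.zeros((n, n))
    sets = [pathways.genes(p) for p in ids]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pathway_distance(sets[i], sets[j])
    return ids, d


def classical_mds(d: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson scaling of a symmetric distance matrix.

    Coordinates come from the ``dims`` largest positive eigenpairs; axes
    whose eigenvalue is non-positive are zero-filled.  Each axis is oriented
    so its largest-magnitude coordinate is positive, making the output
    deterministic up to the inherent rotation ambiguity.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 1e-12:
        raise DegenerateInputError("no positive eigenvalue: degenerate configuration")
    coords = np.zeros((n, dims))
    for k in range(min(dims, n)):
        if evals[k] > 1e-12:
            axis = evecs[:, k] * np.sqrt(evals[k])
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, k] = axis
    return coords


def cluster_pathways(d: np.ndarray, k: int = 5) -> np.ndarray:
    """Average-linkage agglomerative clustering cut to exactly k clusters.

    Labels are renumbered 1..k by increasing index of each cluster's first
    member, so the partition is invariant to input order up to relabeling.
    """
    n = d.shape[0]
    if k < 1 or k > n:
        raise ValueError("k must be between 1 and the number of pathways")
    if n == 1:
        return np.array([1])
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return _canonical_labels(raw)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    order: dict[int, int] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order) + 1
    return np.array([order[lab] for lab in raw])


def embed_pathways(
    pathways: PathwayCollection, ids=None, dims: int = 2, k: int = 5
) -> PathwayEmbedding:
    ids, d = distance_matrix(pathways, ids)
    return PathwayEmbedding(
        pathway_ids=ids,
        distances=d,
        coordinates=classical_mds(d, dims=dims),
        cluster_labels=cluster_pathways(d, k=min(k, len(ids))),
    )


def stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Raw stress: sum of squared differences between input distances and
    embedded Euclidean distances (used to check dims monotonicity)."""
    diff = coords[:, None, :] - coords[None, :, :]
    emb = np.sqrt((diff ** 2).sum(axis=-1))
    return float(((d - emb) ** 2).sum() / 2.0)
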