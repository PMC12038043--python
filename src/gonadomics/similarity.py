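"""Cluster-to-cluster chromatin similarity from snATAC signal.

Per-cell signal is depth-normalized (counts / per-cell fragment total x
median total), the most variable peaks are selected by plain variance,
cluster mean profiles over those peaks are compared by Euclidean distance,
and the distance matrix feeds an agglomerative dendrogram (complete
linkage by default) and nearest-cluster queries. This is the evidence used
to place the steroidogenic progenitor cluster next to the fetal Leydig
cluster in chromatin space.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import Thresholds
from .containers import FeatureMatrix

logger = logging.getLogger("gonadomics")


def depth_normalize(atac: FeatureMatrix, totals=None) -> FeatureMatrix:
    """Scale each cell by (median fragment total / its fragment total).

    ``totals`` defaults to the matrix column sums.
    """
    X = sparse.csr_matrix(atac.X, dtype=float)
    if totals is None:
        totals = np.asarray(X.sum(axis=0)).ravel()
    elif isinstance(totals, pd.Series):
        totals = totals.reindex(atac.cell_ids).to_numpy(dtype=float)
    else:
        totals = np.asarray(totals, dtype=float)
    totals = totals.copy()
    totals[totals == 0] = 1.0
    median = float(np.median(totals))
    X = X.multiply(median / totals).tocsr()
    return FeatureMatrix(X, atac.feature_ids, atac.cell_ids, normalized=True)


def select_variable_peaks(atac: FeatureMatrix, n: int, totals=None) -> list:
    """The ``n`` peaks with highest across-cell variance of normalized signal.

    Deterministic tie-break by peak id. Requesting more peaks than exist
    returns all of them with a warning.
    """
    norm = atac if atac.normalized else depth_normalize(atac, totals)
    X = norm.X
    mean = np.asarray(X.mean(axis=1)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = mean_sq - mean**2
    order = pd.DataFrame({"peak": norm.feature_ids, "var": var})
    order = order.sort_values(["var", "peak"], ascending=[False, True],
                              kind="mergesort")
    if n > len(order):
        logger.warning("requested %d variable peaks but only %d exist",
                       n, len(order))
        n = len(order)
    return order["peak"].head(n).tolist()


def cluster_profiles(
    atac: FeatureMatrix,
    labels,
    peaks,
    totals=None,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Mean depth-normalized signal per cluster over the selected peaks.

    Clusters with fewer than ``min_cluster_cells`` cells are excluded.
    Returns a clusters x peaks DataFrame.
    """
    t = t or Thresholds()
    norm = atac if atac.normalized else depth_normalize(atac, totals)
    norm = norm.subset_features(peaks)
    labels = pd.Series(np.asarray(labels), index=norm.cell_ids)
    profiles = {}
    for cluster, cells in labels.groupby(labels).groups.items():
        if len(cells) < t.min_cluster_cells:
            logger.info("cluster %r has %d cells (< %d); excluded",
                        cluster, len(cells), t.min_cluster_cells)
            continue
        idx = norm.cell_ids.get_indexer(cells)
        profiles[cluster] = np.asarray(norm.X[:, idx].mean(axis=1)).ravel()
    if len(profiles) < 2:
        raise ValueError("need >= 2 clusters passing the size floor")
    return pd.DataFrame(profiles, index=pd.Index(peaks)).T.sort_index()


def cluster_distances(
    atac: FeatureMatrix,
    labels,
    peaks,
    totals=None,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Pairwise Euclidean distances between cluster mean profiles."""
    profiles = cluster_profiles(atac, labels, peaks, totals, t)
    return distances_from_profiles(profiles)


def distances_from_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    M = profiles.to_numpy(dtype=float)
    diff = M[:, None, :] - M[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(D, index=profiles.index, columns=profiles.index)


def build_dendrogram(distances: pd.DataFrame, method: str = "complete"):
    """Agglomerative clustering of the distance matrix.

    Returns (linkage matrix in scipy format, leaf labels in input order).
    ``method`` is one of complete | average | single.
    """
    if len(distances) < 2:
        raise ValueError("dendrogram needs >= 2 clusters")
    condensed = squareform(distances.to_numpy(dtype=float), checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return Z, list(distances.index)


def dendrogram_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def nearest_cluster(distances: pd.DataFrame, target) -> tuple:
    """The non-target cluster at minimal distance from ``target``.

    Ties break deterministically by cluster id order.
    """
    if target not in distances.index:
        raise KeyError(f"cluster {target!r} absent from distance matrix")
    row = distances.loc[target].drop(target)
    row = row.loc[sorted(row.index, key=str)]
    best = row.idxmin()
    return best, float(row[best])
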