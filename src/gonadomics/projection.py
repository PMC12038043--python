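"""Bulk-DEG to single-nucleus empirical projection.

Up- and down-regulated gene lists from a bulk knockout-vs-control contrast
are projected onto single-nucleus clusters: per-cluster average normalized
expression, per-gene z-scoring across clusters, hierarchical gene grouping
with a minimum-group-size rule (largest k whose smallest group still holds
>= 2% of the genes), and the "most affected" population call — a cluster
where more than 20% of the DEGs have z > 1, both comparisons strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .config import Thresholds
from .containers import FeatureMatrix
from .differential import log_normalize

logger = logging.getLogger("gonadomics")


@dataclass
class ProjectionResult:
    """Projection of one DEG direction onto the cluster landscape."""

    deg_list_id: str
    z: pd.DataFrame                     # genes x clusters
    constant_rows: pd.Index
    gene_groups: pd.Series              # group id per gene
    k_selected: int
    affected_fractions: pd.Series       # per-cluster fraction of DEGs at z > 1
    affected: list = field(default_factory=list)
    row_order: list = field(default_factory=list)


def cluster_means(
    rna: FeatureMatrix,
    labels,
    genes,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Mean normalized expression of the DEG list per retained cluster.

    Clusters below ``min_cluster_cells`` are dropped (mirroring the
    exclusion of a two-cell cluster); DEGs absent from the matrix are
    dropped with a logged count.
    """
    t = t or Thresholds()
    genes = list(genes)
    present = [g for g in genes if g in set(rna.feature_ids)]
    if not present:
        raise ValueError("none of the requested genes are in the matrix")
    if len(present) < len(genes):
        logger.info("%d of %d DEGs absent from the matrix; dropped",
                    len(genes) - len(present), len(genes))
    norm = log_normalize(rna).subset_features(present)
    labels = pd.Series(np.asarray(labels), index=norm.cell_ids)
    cols = {}
    for cluster, cells in labels.groupby(labels).groups.items():
        if len(cells) < t.min_cluster_cells:
            logger.info("cluster %r has %d cells (< %d); ignored",
                        cluster, len(cells), t.min_cluster_cells)
            continue
        idx = norm.cell_ids.get_indexer(cells)
        cols[cluster] = np.asarray(norm.X[:, idx].mean(axis=1)).ravel()
    out = pd.DataFrame(cols, index=pd.Index(present, name="gene_id"))
    return out[sorted(out.columns, key=str)]


def zscore_rows(means: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Per-gene z-scores across clusters (sample s.d., n-1 denominator).

    Constant rows become all-zero and are returned in the flagged index.
    """
    if means.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 clusters")
    M = means.to_numpy(dtype=float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    Z = (M - mu) / sd
    Z[constant, :] = 0.0
    flagged = means.index[constant]
    if len(flagged):
        logger.info("%d constant expression rows flagged (all-zero z)",
                    len(flagged))
    return pd.DataFrame(Z, index=means.index, columns=means.columns), flagged


def affected_populations(
    z: pd.DataFrame, t: Thresholds | None = None
) -> tuple[list, pd.Series]:
    """Clusters where the fraction of DEGs with z > 1 strictly exceeds 0.20."""
    t = t or Thresholds()
    fractions = (z > t.projection_z_cut).sum(axis=0) / len(z)
    fractions.name = "fraction_z_gt_1"
    affected = [c for c in z.columns if fractions[c] > t.projection_deg_frac]
    return affected, fractions


def group_genes(
    z: pd.DataFrame, t: Thresholds | None = None
) -> tuple[pd.Series, int, list]:
    """Hierarchical gene groups at the largest admissible dendrogram cut.

    Rows are clustered (Euclidean, complete linkage). Among cuts
    k = 2, 3, ..., the selected k is the largest whose smallest group
    holds >= ceil(min_group_frac x n_genes) genes; if none qualifies,
    k = 1. Returns (group id per gene, k, dendrogram leaf order).
    """
    t = t or Thresholds()
    n = len(z)
    if n < 2:
        raise ValueError("grouping needs >= 2 genes")
    Zlink = hierarchy.linkage(pdist(z.to_numpy(dtype=float)), method="complete")
    floor = int(np.ceil(t.projection_min_group_frac * n))
    cuts = hierarchy.cut_tree(Zlink)  # n x n matrix, column j = n - j groups
    # identical rows merge at height 0; cuts separating them are not
    # meaningful groupings, so cap k at the number of distinguishable rows
    k_max = n - int((Zlink[:, 2] <= 1e-12).sum())
    k_selected = 1
    best = np.zeros(n, dtype=int)
    for k in range(2, k_max + 1):
        assignment = cuts[:, n - k]
        sizes = np.bincount(assignment)
        if sizes.min() >= floor:
            k_selected = k
            best = assignment
    groups = pd.Series(best, index=z.index, name="group")
    leaf_order = [z.index[i] for i in hierarchy.leaves_list(Zlink)]
    return groups, k_selected, leaf_order


def project(
    bulk_de: pd.DataFrame,
    rna: FeatureMatrix,
    labels,
    t: Thresholds | None = None,
) -> dict[str, ProjectionResult]:
    """Run the projection separately for the up and down bulk DEG lists.

    ``bulk_de`` needs feature_id, adj_p and direction columns; only genes
    at adj_p < 0.05 enter. Row order in the result follows the dendrogram
    leaf order (heatmap-ready); columns are sorted cluster ids.
    """
    t = t or Thresholds()
    results: dict[str, ProjectionResult] = {}
    sig = bulk_de[bulk_de["adj_p"] < t.adj_p_max]
    for direction, label in (("up_in_a", "up"), ("up_in_b", "down")):
        genes = sig.loc[sig["direction"] == direction, "feature_id"].tolist()
        if not genes:
            logger.warning("no significant %s-regulated genes; skipped", label)
            continue
        means = cluster_means(rna, labels, genes, t)
        z, constant = zscore_rows(means)
        groups, k, leaf_order = group_genes(z, t)
        affected, fractions = affected_populations(z, t)
        results[label] = ProjectionResult(
            deg_list_id=label,
            z=z,
            constant_rows=constant,
            gene_groups=groups,
            k_selected=k,
            affected_fractions=fractions,
            affected=affected,
            row_order=leaf_order,
        )
    return results
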