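"""Topology-associated gene (TAG) analysis.

The statistical heart of the pipeline: select genes (at most 25% zero
reads, top 150 by log1p-count variance), log-transform genes and ITFs,
correlate every gene with every ITF (Pearson, across spots), k-means
cluster both axes of the correlation matrix with an elbow-selected k
(baseline 10 when the elbow is undecidable), and match each ITF cluster to
its most-similar TAG cluster by block-mean correlation.

All filtered genes are organized into TAG clusters; the per-gene max |PCC|
is reported so users can threshold "correlates well" as they see fit.
Clustering operates on correlation profiles (rows for genes, columns for
ITFs), not on raw expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "GeneFilterConfig",
    "CorrelationResult",
    "ClusterSolution",
    "BlockSimilarity",
    "filter_genes",
    "log_transform",
    "correlation_matrix",
    "cluster_axis",
    "block_similarity",
    "tag_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneFilterConfig:
    """Zero-read cap and variable-gene count used for gene selection."""

    max_zero_frac: float = 0.25
    top_n: int = 150

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_zero_frac <= 1.0:
            raise ValueError("max_zero_frac must be in [0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class CorrelationResult:
    """Genes x ITFs Pearson matrix; degenerate (zero-variance) rows and
    columns are dropped and recorded rather than producing NaNs."""

    matrix: pd.DataFrame
    dropped_genes: list[str] = field(default_factory=list)
    dropped_itfs: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def itf_names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ClusterSolution:
    """K-means clustering of one axis of the correlation matrix."""

    axis: str  # "genes" or "itfs"
    k_chosen: int
    assignments: pd.Series  # item -> cluster id in 1..k
    wcss_by_k: dict[int, float]
    seed: int


@dataclass
class BlockSimilarity:
    """Mean PCC per (ITF cluster, TAG cluster) block and the induced
    most-similar TAG cluster for every ITF cluster (ties -> lower id)."""

    block_means: pd.DataFrame  # index: ITF cluster id, columns: gene cluster id
    most_similar: dict[int, int]


def filter_genes(counts: pd.DataFrame, cfg: GeneFilterConfig | None = None) -> list[str]:
    """Genes with zero-fraction <= cap, ranked by decreasing variance of
    log1p counts (ties by gene id), truncated to ``cfg.top_n``.

    ``counts`` is spots x genes.  Raises when no gene qualifies.
    """
    cfg = cfg or GeneFilterConfig()
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    zero_frac = (counts == 0).mean(axis=0)
    qualifying = zero_frac[zero_frac <= cfg.max_zero_frac].index
    if len(qualifying) == 0:
        raise ValueError(
            f"no gene passes the {cfg.max_zero_frac:.0%} zero-read filter"
        )
    variances = np.log1p(counts[qualifying]).var(axis=0, ddof=1)
    ranked = variances.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[: cfg.top_n])


def log_transform(matrix: pd.DataFrame | np.ndarray):
    """Elementwise log(1 + x); rejects negative entries."""
    arr = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if (arr < 0).any():
        raise ValueError("log transform requires non-negative entries")
    return np.log1p(matrix)


def correlation_matrix(genes_log: pd.DataFrame, itfs_log: pd.DataFrame) -> CorrelationResult:
    """Sample Pearson correlation of every gene with every ITF across spots.

    Both inputs are spots x variables and must share the spot index in the
    same order.  Zero-variance columns on either side are dropped and
    listed in the result.
    """
    if len(genes_log) != len(itfs_log) or not (genes_log.index == itfs_log.index).all():
        raise ValueError("gene and ITF tables must share the same spot index")
    n = len(genes_log)
    if n < 3:
        raise ValueError("correlation needs at least 3 spots")
    g_std = genes_log.std(axis=0, ddof=0)
    f_std = itfs_log.std(axis=0, ddof=0)
    dropped_genes = list(g_std.index[g_std == 0])
    dropped_itfs = list(f_std.index[f_std == 0])
    G = genes_log.drop(columns=dropped_genes)
    F = itfs_log.drop(columns=dropped_itfs)
    Gz = (G - G.mean(axis=0)) / G.std(axis=0, ddof=0)
    Fz = (F - F.mean(axis=0)) / F.std(axis=0, ddof=0)
    corr = pd.DataFrame(
        Gz.to_numpy().T @ Fz.to_numpy() / n, index=G.columns, columns=F.columns
    )
    corr = corr.clip(-1.0, 1.0)
    if dropped_genes or dropped_itfs:
        log.info(
            "correlation_matrix dropped %d zero-variance genes, %d ITFs",
            len(dropped_genes), len(dropped_itfs),
        )
    return CorrelationResult(corr, dropped_genes, dropped_itfs)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Map raw k-means labels to 1..k in order of first appearance, so
    cluster numbering is stable and contiguous."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_axis(
    corr: CorrelationResult,
    axis: str,
    k_range: tuple[int, int] = (2, 12),
    seed: int = 0,
    k_baseline: int = 10,
) -> ClusterSolution:
    """K-means over correlation profiles with elbow-selected k.

    Profiles are matrix rows for ``axis="genes"`` and columns for
    ``axis="itfs"``.  The within-cluster sum of squares (WCSS) is computed
    for every k in ``k_range``; k is chosen as the maximizer of the second
    difference of WCSS over interior k.  When no interior k exists the
    baseline (default 10, clipped into the range) is used.
    """
    if axis == "genes":
        profiles = corr.matrix.to_numpy()
        items = corr.gene_ids
    elif axis == "itfs":
        profiles = corr.matrix.to_numpy().T
        items = corr.itf_names
    else:
        raise ValueError("axis must be 'genes' or 'itfs'")
    k_lo, k_hi = k_range
    n_items = len(items)
    if k_lo < 2 or k_hi < k_lo or k_hi > n_items:
        raise ValueError(f"k_range {k_range} outside [2, {n_items}]")

    wcss: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels_by_k[k] = km.fit_predict(profiles)
        wcss[k] = float(km.inertia_)

    interior = [k for k in range(k_lo + 1, k_hi)]
    if interior:
        # elbow: sharpest bend = max second difference of the WCSS curve
        second_diff = {
            k: wcss[k - 1] - 2 * wcss[k] + wcss[k + 1] for k in interior
        }
        k_chosen = min(second_diff, key=lambda k: (-second_diff[k], k))
    else:
        k_chosen = int(np.clip(k_baseline, k_lo, k_hi))
    assignments = pd.Series(
        _relabel_by_first_occurrence(labels_by_k[k_chosen]),
        index=items, name="cluster",
    )
    return ClusterSolution(axis=axis, k_chosen=k_chosen, assignments=assignments,
                           wcss_by_k=wcss, seed=seed)


def block_similarity(
    corr: CorrelationResult,
    gene_clusters: ClusterSolution,
    itf_clusters: ClusterSolution,
) -> BlockSimilarity:
    """Mean PCC of each (ITF cluster x TAG cluster) block of the matrix.

    ``most_similar`` maps every ITF cluster to the TAG cluster maximizing
    the block mean, ties resolved toward the lower cluster id.
    """
    g = gene_clusters.assignments.reindex(corr.gene_ids)
    f = itf_clusters.assignments.reindex(corr.itf_names)
    if g.isna().any() or f.isna().any():
        raise ValueError("cluster assignments do not cover the matrix axes")
    gene_ids_by_cluster = {c: g.index[g == c] for c in sorted(g.unique())}
    itf_ids_by_cluster = {c: f.index[f == c] for c in sorted(f.unique())}
    block = pd.DataFrame(
        index=sorted(itf_ids_by_cluster), columns=sorted(gene_ids_by_cluster),
        dtype=float,
    )
    for fc, itf_ids in itf_ids_by_cluster.items():
        if len(itf_ids) == 0:
            log.warning("ITF cluster %d is empty; excluded", fc)
            continue
        for gc, gene_ids in gene_ids_by_cluster.items():
            if len(gene_ids) == 0:
                log.warning("gene cluster %d is empty; excluded", gc)
                continue
            block.loc[fc, gc] = float(
                corr.matrix.loc[gene_ids, itf_ids].to_numpy().mean()
            )
    block = block.dropna(axis=0, how="all").dropna(axis=1, how="all")
    most_similar = {
        int(fc): int(block.loc[fc].astype(float).idxmax())
        for fc in block.index
    }
    return BlockSimilarity(block_means=block, most_similar=most_similar)


def tag_report(
    corr: CorrelationResult,
    gene_clusters: ClusterSolution,
    itf_clusters: ClusterSolution,
    similarity: BlockSimilarity,
) -> dict[str, pd.DataFrame]:
    """Assemble the output tables of the TAG analysis.

    * ``genes``: per gene, its TAG cluster, max |PCC| over ITFs and the
      ITF attaining it;
    * ``tag_clusters``: one row per (cluster, gene) pair -- the TAG sets;
    * ``similarity``: block means plus the most-similar TAG cluster per
      ITF cluster;
    * ``heatmap_order``: genes and ITFs sorted by cluster then name, the
      row/column order used for plotting.
    """
    mat = corr.matrix
    abs_mat = mat.abs()
    best_itf = abs_mat.idxmax(axis=1)
    genes = pd.DataFrame({
        "gene_id": mat.index,
        "cluster": gene_clusters.assignments.reindex(mat.index).to_numpy(),
        "max_abs_pcc": abs_mat.max(axis=1).to_numpy(),
        "best_itf": best_itf.to_numpy(),
        "best_pcc": mat.to_numpy()[
            np.arange(len(mat)), mat.columns.get_indexer(best_itf)
        ],
    }).reset_index(drop=True)

    tag_clusters = (
        genes[["cluster", "gene_id"]]
        .sort_values(["cluster", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )

    sim = similarity.block_means.copy()
    sim.index.name = "itf_cluster"
    sim_table = sim.reset_index().melt(
        id_vars="itf_cluster", var_name="tag_cluster", value_name="mean_pcc"
    )
    sim_table["most_similar"] = [
        int(similarity.most_similar.get(int(fc), -1)) == int(tc)
        for fc, tc in zip(sim_table["itf_cluster"], sim_table["tag_cluster"])
    ]

    gene_order = genes.sort_values(
        ["cluster", "gene_id"], kind="stable")["gene_id"]
    itf_assign = itf_clusters.assignments.reindex(mat.columns)
    itf_order = itf_assign.sort_index().sort_values(kind="stable").index
    heatmap_order = pd.DataFrame({
        "axis": ["genes"] * len(gene_order) + ["itfs"] * len(itf_order),
        "item": list(gene_order) + list(itf_order),
        "position": list(range(len(gene_order))) + list(range(len(itf_order))),
    })
    return {
        "genes": genes,
        "tag_clusters": tag_clusters,
        "similarity": sim_table,
        "heatmap_order": heatmap_order,
    }
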