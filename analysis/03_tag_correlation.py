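#!/usr/bin/env python
"""Identify topology-associated genes: filter to the top 150 variable
genes with <= 25% zero reads, correlate their log1p expression with the
log1p ITFs, cluster both axes of the correlation matrix (k-means, elbow
over k = 2..12), match ITF clusters to TAG clusters, and draw the
cluster-ordered heatmap."""

from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from topotag.stio import read_expression
from topotag.tag_analysis import (
    GeneFilterConfig,
    block_similarity,
    cluster_axis,
    correlation_matrix,
    filter_genes,
    log_transform,
    tag_report,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    slide_dir = RESULTS / "slide"
    expr = read_expression(slide_dir / "matrix.mtx", slide_dir / "barcodes.tsv",
                           slide_dir / "features.tsv")
    itf = pd.read_csv(RESULTS / "itf_matrix.tsv", sep="\t", index_col="spot_id")

    selected = filter_genes(expr.counts, GeneFilterConfig())
    corr = correlation_matrix(
        log_transform(expr.counts[selected]),
        log_transform(itf.loc[expr.counts.index]),
    )
    print(f"selected {len(selected)} genes; correlation matrix "
          f"{corr.matrix.shape[0]} genes x {corr.matrix.shape[1]} ITFs "
          f"({len(corr.dropped_itfs)} constant ITFs dropped)")

    gsol = cluster_axis(corr, "genes", (2, 12), seed=SEED + 1)
    fsol = cluster_axis(corr, "itfs", (2, 12), seed=SEED + 1)
    sim = block_similarity(corr, gsol, fsol)
    report = tag_report(corr, gsol, fsol, sim)
    print(f"elbow chose {gsol.k_chosen} TAG clusters and "
          f"{fsol.k_chosen} ITF clusters")
    for fc, tc in sim.most_similar.items():
        print(f"  ITF cluster {fc} is most similar to TAG cluster {tc} "
              f"(mean PCC {sim.block_means.loc[fc, tc]:+.3f})")

    corr.matrix.to_csv(RESULTS / "correlation_matrix.tsv", sep="\t",
                       index_label="gene_id", float_format="%.10g")
    report["genes"].to_csv(RESULTS / "tag_genes.tsv", sep="\t", index=False,
                           float_format="%.10g")
    report["tag_clusters"].to_csv(RESULTS / "tag_clusters.tsv", sep="\t",
                                  index=False)
    report["similarity"].to_csv(RESULTS / "block_similarity.tsv", sep="\t",
                                index=False, float_format="%.10g")

    # heatmap in cluster order with cluster bands
    order = report["heatmap_order"]
    gene_order = order.loc[order["axis"] == "genes", "item"]
    itf_order = order.loc[order["axis"] == "itfs", "item"]
    mat = corr.matrix.loc[gene_order, itf_order]
    fig, ax = plt.subplots(figsize=(10, 7))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-1, vmax=1, interpolation="nearest")
    for pos in gsol.assignments.reindex(gene_order).diff().to_numpy().nonzero()[0]:
        ax.axhline(pos - 0.5, color="k", lw=0.6)
    for pos in fsol.assignments.reindex(itf_order).diff().to_numpy().nonzero()[0]:
        ax.axvline(pos - 0.5, color="k", lw=0.6)
    ax.set_xlabel("ITFs (cluster-ordered)")
    ax.set_ylabel("genes (cluster-ordered)")
    fig.colorbar(im, label="Pearson r")
    fig.tight_layout()
    fig.savefig(RESULTS / "correlation_heatmap.png", dpi=150)
    print(f"written: correlation_matrix.tsv, tag_genes.tsv, tag_clusters.tsv, "
          f"block_similarity.tsv, correlation_heatmap.png in {RESULTS}")


if __name__ == "__main__":
    main()
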