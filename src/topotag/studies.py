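"""Reusable synthetic-study procedures.

Each study builds a slide with known ground truth, runs the relevant part
of the pipeline, and measures how well the truth is recovered.  They are
shared by the analysis drivers, the acceptance script, and the test
suite, so every reported number comes from one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .enrichment import enrich_clusters
from .prediction import PredictionTask, compare_learners, loocv_predict
from .synthetic import SyntheticSlide, default_gene_models, generate_slide
from .tag_analysis import (
    GeneFilterConfig,
    cluster_axis,
    correlation_matrix,
    filter_genes,
    log_transform,
)
from .vectorize import VectorizationGrid, compute_itf_table

__all__ = [
    "slide_with_itfs",
    "ring_gene_auroc",
    "tag_enrichment_study",
    "prediction_study",
    "synthetic_gmt",
]


def slide_with_itfs(
    seed: int,
    n_spots: int = 400,
    n_genes: int = 300,
    n_ring_coupled: int = 30,
    beta: float = 1.5,
    patch_size_px: int = 350,
) -> tuple[SyntheticSlide, pd.DataFrame]:
    """Generate a slide under the default study conditions and compute its
    ITF table (400 spots, 300 genes, 30 ring-coupled at beta = 1.5)."""
    models = default_gene_models(
        n_genes=n_genes, n_ring_coupled=n_ring_coupled, beta=beta,
        rng_seed=seed,
    )
    slide = generate_slide(
        n_spots=n_spots, gene_models=models, rng_seed=seed,
        patch_size_px=patch_size_px,
    )
    grid = VectorizationGrid.for_patch(patch_size_px)
    itf = compute_itf_table(slide.bundle.point_clouds, grid)
    return slide, itf


def ring_gene_auroc(slide: SyntheticSlide, itf: pd.DataFrame) -> float:
    """How well max |PCC| against H1 ITFs separates ring-coupled genes.

    Every gene is ranked by its maximum absolute Pearson correlation with
    any H1 feature; the AUROC scores that ranking against the known
    coupled/uncoupled labels.
    """
    counts = slide.bundle.expression.counts
    h1 = itf.loc[counts.index, [c for c in itf.columns if c.startswith("H1_")]]
    corr = correlation_matrix(log_transform(counts), log_transform(h1))
    max_abs = corr.matrix.abs().max(axis=1)
    # genes dropped for zero variance cannot be ranked; score them at 0
    max_abs = max_abs.reindex(counts.columns).fillna(0.0)
    labels = np.array([g in set(slide.coupled_genes) for g in counts.columns])
    return float(roc_auc_score(labels, max_abs.to_numpy()))


def synthetic_gmt(slide: SyntheticSlide, n_decoys: int = 20,
                  seed: int = 0) -> dict[str, set[str]]:
    """Planted term = the coupled genes, plus random decoy terms."""
    rng = np.random.default_rng(seed + 17)
    genes = [g.gene_id for g in slide.gene_models]
    terms: dict[str, set[str]] = {"PLANTED:coupled": set(slide.coupled_genes)}
    for i in range(n_decoys):
        size = int(rng.integers(10, max(11, len(genes) // 5)))
        terms[f"DECOY:{i + 1:03d}"] = set(rng.choice(genes, size=size, replace=False))
    return terms


def tag_enrichment_study(
    slide: SyntheticSlide,
    itf: pd.DataFrame,
    k_range: tuple[int, int] = (2, 12),
    n_decoys: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Full TAG procedure on one slide, then enrichment of the recovered
    TAG cluster (the gene cluster holding most coupled genes) against a
    GMT with the planted term and random decoys.

    Returns the planted term's rank (1 = first) in that cluster's
    enrichment list, plus bookkeeping.
    """
    counts = slide.bundle.expression.counts
    cfg = GeneFilterConfig()
    selected = filter_genes(counts, cfg)
    corr = correlation_matrix(
        log_transform(counts[selected]),
        log_transform(itf.loc[counts.index]),
    )
    gsol = cluster_axis(corr, "genes", k_range, seed=slide.seed + 1)
    coupled = set(slide.coupled_genes)
    overlap_by_cluster = gsol.assignments.groupby(gsol.assignments).apply(
        lambda s: len(set(s.index) & coupled)
    )
    recovered = int(overlap_by_cluster.idxmax())
    query = set(gsol.assignments.index[gsol.assignments == recovered])

    zero_frac = (counts == 0).mean(axis=0)
    universe = set(zero_frac.index[zero_frac <= cfg.max_zero_frac])
    gmt = synthetic_gmt(slide, n_decoys=n_decoys, seed=slide.seed)
    results = enrich_clusters({recovered: query}, gmt, universe, alpha=alpha)
    ranked = [r.term_id for r in results[recovered]]
    return {
        "planted_term_rank": ranked.index("PLANTED:coupled") + 1,
        "recovered_cluster": recovered,
        "recovered_cluster_size": len(query),
        "coupled_in_recovered": int(overlap_by_cluster.max()),
        "k_chosen": gsol.k_chosen,
        "top_adjusted_p": results[recovered][0].p_adjusted,
        "significant": results[recovered][0].significant,
    }


def prediction_study(
    seed: int,
    n_spots: int = 200,
    n_itfs: int = 12,
    compare_with: str | None = None,
) -> dict:
    """LOOCV prediction on a slide with two constructed genes: one an
    exact linear function of a single H1 ITF, one independent noise.

    Returns the per-gene PCCs (the determined gene should predict nearly
    perfectly, the independent one not at all) and, optionally, a paired
    comparison against a second learner.
    """
    slide, itf = slide_with_itfs(seed, n_spots=n_spots, n_genes=20,
                                 n_ring_coupled=0)
    itf = itf.loc[slide.bundle.expression.counts.index]
    h1_var = itf[[c for c in itf.columns if c.startswith("H1_")]].var(axis=0)
    anchor = h1_var.idxmax()
    rng = np.random.default_rng(seed + 101)
    expr = pd.DataFrame({
        "DETERMINED": 5.0 * itf[anchor],
        "INDEPENDENT": rng.negative_binomial(2, 2 / 7, size=n_spots).astype(float),
    }, index=itf.index)
    subset = [anchor] + [
        c for c in itf.var(axis=0).sort_values(ascending=False).index
        if c != anchor
    ][: n_itfs - 1]
    task = PredictionTask(tuple(subset), ("DETERMINED", "INDEPENDENT"), seed=seed)
    cv = loocv_predict(itf, expr, task)
    out = {
        "pcc_determined": float(cv.pcc["DETERMINED"]),
        "pcc_independent": float(cv.pcc["INDEPENDENT"]),
        "anchor_itf": anchor,
        "learner": cv.learner,
    }
    if compare_with:
        cv_b = loocv_predict(
            itf, expr,
            PredictionTask(tuple(subset), ("DETERMINED", "INDEPENDENT"),
                           learner=compare_with, seed=seed),
        )
        diff, pval = compare_learners(cv, cv_b)
        out["learner_mean_pcc_diff"] = diff
        out["learner_comparison_p"] = pval
    return out
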