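"""Stage orchestration with a reproducibility manifest.

``run_all`` executes simulate -> features -> correlate -> cluster ->
enrich -> predict, writing every product as TSV plus a JSON manifest
(config snapshot, seed, file checksums, output list).  Re-running with an
unchanged config skips stages whose outputs are present and whose recorded
checksums still match, so partial reruns are cheap and a completed run is
a no-op.

The global seed is expanded per stage by fixed offsets (simulate +0,
cluster +1, predict +2), keeping stages individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich_clusters
from .prediction import DEFAULT_LEARNER, PredictionTask, compare_learners, loocv_predict
from .stio import (
    PipelineConfig,
    read_expression,
    read_gmt,
    read_point_clouds,
    write_gmt,
)
from .synthetic import default_gene_models, generate_slide, write_slide
from .tag_analysis import (
    GeneFilterConfig,
    block_similarity,
    cluster_axis,
    correlation_matrix,
    filter_genes,
    log_transform,
    tag_report,
)
from .vectorize import VectorizationGrid, compute_itf_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_all", "load_config"]

_STAGES = ("simulate", "features", "correlate", "cluster", "enrich", "predict")


@dataclasses.dataclass
class RunConfig:
    """Everything a full run needs; serializable to/from YAML."""

    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)
    n_spots: int = 120
    n_genes: int = 300
    n_ring_coupled: int = 30
    beta: float = 1.5
    dispersion: float = 2.0
    gmt_path: str | None = None          # None: use the synthetic GMT
    n_decoy_terms: int = 20
    predict_n_itfs: int = 12
    predict_n_genes: int = 19
    predict_learner: str = DEFAULT_LEARNER
    compare_learner: str | None = None
    stages: tuple[str, ...] = _STAGES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def load_config(path: str | Path | None = None, seed: int | None = None,
                **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    pipe_kwargs = data.pop("pipeline", {})
    if seed is not None:
        pipe_kwargs["seed"] = seed
    if "k_range" in pipe_kwargs:
        pipe_kwargs["k_range"] = tuple(pipe_kwargs["k_range"])
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return RunConfig(pipeline=PipelineConfig(**pipe_kwargs), **data)


class RunManifest:
    """Config snapshot, checksums, and output list of one run directory."""

    def __init__(self, out_dir: Path):
        self.path = Path(out_dir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "stages": {}}

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")

    @staticmethod
    def checksum(path: Path) -> str:
        return hashlib.sha256(path.read_bytes()).hexdigest()

    def stage_fresh(self, stage: str, config_key: str, outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry or entry.get("config") != config_key:
            return False
        recorded = entry.get("outputs", {})
        for f in outputs:
            if not f.exists() or recorded.get(f.name) != self.checksum(f):
                return False
        return True

    def record(self, stage: str, config_key: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "config": config_key,
            "outputs": {f.name: self.checksum(f) for f in outputs},
        }
        self.save()

    def all_outputs(self) -> list[str]:
        return sorted(
            name for entry in self.data["stages"].values()
            for name in entry.get("outputs", {})
        )


def _config_key(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages into ``out_dir``; returns the path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config
    pcfg = cfg.pipeline
    key = _config_key(cfg)
    manifest = RunManifest(out_dir)
    manifest.data["config"] = cfg.to_dict()
    manifest.save()

    # fail fast on config errors before any compute
    if "enrich" in cfg.stages and cfg.gmt_path is not None:
        if not Path(cfg.gmt_path).exists():
            raise FileNotFoundError(f"GMT file not found: {cfg.gmt_path}")

    slide_dir = out_dir / "slide"
    slide_files = [
        slide_dir / n
        for n in ("matrix.mtx", "barcodes.tsv", "features.tsv",
                  "tissue_positions.csv", "point_clouds.tsv",
                  "ground_truth_genes.tsv", "ground_truth_spots.tsv")
    ]
    gmt_path = Path(cfg.gmt_path) if cfg.gmt_path else out_dir / "synthetic_terms.gmt"

    if "simulate" in cfg.stages:
        sim_files = slide_files + ([] if cfg.gmt_path else [gmt_path])
        if manifest.stage_fresh("simulate", key, sim_files):
            log.info("simulate: outputs fresh, skipped")
        else:
            models = default_gene_models(
                n_genes=cfg.n_genes, n_ring_coupled=cfg.n_ring_coupled,
                beta=cfg.beta, dispersion=cfg.dispersion, rng_seed=pcfg.seed,
            )
            slide = generate_slide(
                n_spots=cfg.n_spots, gene_models=models,
                rng_seed=pcfg.seed, patch_size_px=pcfg.patch_size_px,
            )
            write_slide(slide, slide_dir)
            if cfg.gmt_path is None:
                _write_synthetic_gmt(slide, gmt_path, cfg.n_decoy_terms, pcfg.seed)
            manifest.record("simulate", key, sim_files)
            log.info("simulate: %d spots, %d genes", cfg.n_spots, cfg.n_genes)

    itf_path = out_dir / "itf_matrix.tsv"
    if "features" in cfg.stages:
        if manifest.stage_fresh("features", key, [itf_path]):
            log.info("features: outputs fresh, skipped")
        else:
            clouds = read_point_clouds(slide_dir / "point_clouds.tsv")
            grid = VectorizationGrid.for_patch(
                pcfg.patch_size_px, pcfg.n_birth_bins, pcfg.n_pers_bins)
            itf = compute_itf_table(clouds, grid)
            itf.to_csv(itf_path, sep="\t", index_label="spot_id",
                       float_format="%.10g")
            manifest.record("features", key, [itf_path])
            log.info("features: %s ITFs per spot", itf.shape[1])

    corr_path = out_dir / "correlation_matrix.tsv"
    genes_path = out_dir / "selected_genes.tsv"
    if "correlate" in cfg.stages:
        if manifest.stage_fresh("correlate", key, [corr_path, genes_path]):
            log.info("correlate: outputs fresh, skipped")
        else:
            expr = read_expression(slide_dir / "matrix.mtx",
                                   slide_dir / "barcodes.tsv",
                                   slide_dir / "features.tsv")
            itf = pd.read_csv(itf_path, sep="\t", index_col="spot_id")
            fcfg = GeneFilterConfig(pcfg.max_zero_frac, pcfg.top_n_genes)
            selected = filter_genes(expr.counts, fcfg)
            pd.Series(selected, name="gene_id").to_csv(
                genes_path, sep="\t", index=False)
            corr = correlation_matrix(
                log_transform(expr.counts[selected].loc[itf.index]),
                log_transform(itf),
            )
            corr.matrix.to_csv(corr_path, sep="\t", index_label="gene_id",
                               float_format="%.10g")
            manifest.record("correlate", key, [corr_path, genes_path])
            log.info("correlate: %d genes x %d ITFs", *corr.matrix.shape)

    cluster_files = [out_dir / "gene_clusters.tsv", out_dir / "itf_clusters.tsv",
                     out_dir / "block_similarity.tsv", out_dir / "tag_genes.tsv"]
    if "cluster" in cfg.stages:
        if manifest.stage_fresh("cluster", key, cluster_files):
            log.info("cluster: outputs fresh, skipped")
        else:
            corr = _read_corr(corr_path)
            k_range = _clip_k_range(pcfg.k_range, corr)
            gsol = cluster_axis(corr, "genes", k_range, seed=pcfg.seed + 1,
                                k_baseline=pcfg.k_baseline)
            fsol = cluster_axis(corr, "itfs", k_range, seed=pcfg.seed + 1,
                                k_baseline=pcfg.k_baseline)
            sim = block_similarity(corr, gsol, fsol)
            report = tag_report(corr, gsol, fsol, sim)
            _write_assignments(gsol, cluster_files[0])
            _write_assignments(fsol, cluster_files[1])
            report["similarity"].to_csv(cluster_files[2], sep="\t", index=False,
                                        float_format="%.10g")
            report["genes"].to_csv(cluster_files[3], sep="\t", index=False,
                                   float_format="%.10g")
            manifest.record("cluster", key, cluster_files)
            log.info("cluster: k_genes=%d, k_itfs=%d", gsol.k_chosen, fsol.k_chosen)

    enrich_path = out_dir / "enrichment.tsv"
    if "enrich" in cfg.stages:
        if manifest.stage_fresh("enrich", key, [enrich_path]):
            log.info("enrich: outputs fresh, skipped")
        else:
            expr = read_expression(slide_dir / "matrix.mtx",
                                   slide_dir / "barcodes.tsv",
                                   slide_dir / "features.tsv")
            zero_frac = (expr.counts == 0).mean(axis=0)
            universe = set(zero_frac.index[zero_frac <= pcfg.max_zero_frac])
            clusters = pd.read_csv(cluster_files[0], sep="\t")
            tag_sets = {
                int(c): set(sub["item"])
                for c, sub in clusters.groupby("cluster")
            }
            gmt = read_gmt(gmt_path)
            results = enrich_clusters(tag_sets, gmt, universe, alpha=pcfg.alpha)
            rows = [
                {"cluster": c, "term_id": r.term_id, "overlap": r.overlap,
                 "query_size": r.query_size, "term_size": r.term_size,
                 "universe_size": r.universe_size, "p_value": r.p_value,
                 "p_adjusted": r.p_adjusted, "significant": int(r.significant)}
                for c, rlist in sorted(results.items()) for r in rlist
            ]
            pd.DataFrame(rows).to_csv(enrich_path, sep="\t", index=False,
                                      float_format="%.10g")
            manifest.record("enrich", key, [enrich_path])
            log.info("enrich: %d clusters tested", len(results))

    predict_path = out_dir / "prediction.tsv"
    if "predict" in cfg.stages:
        if manifest.stage_fresh("predict", key, [predict_path]):
            log.info("predict: outputs fresh, skipped")
        else:
            expr = read_expression(slide_dir / "matrix.mtx",
                                   slide_dir / "barcodes.tsv",
                                   slide_dir / "features.tsv")
            itf = pd.read_csv(itf_path, sep="\t", index_col="spot_id")
            corr = _read_corr(corr_path)
            genes, itfs = select_prediction_subsets(
                corr, cfg.predict_n_genes, cfg.predict_n_itfs)
            task = PredictionTask(tuple(itfs), tuple(genes),
                                  learner=cfg.predict_learner,
                                  seed=pcfg.seed + 2)
            cv = loocv_predict(itf.loc[expr.counts.index], expr.counts, task)
            table = pd.DataFrame({
                "gene_id": cv.pcc.index, "pcc": cv.pcc.to_numpy(),
                "n_spots": len(itf), "learner": cv.learner, "seed": cv.seed,
            })
            if cfg.compare_learner:
                task_b = dataclasses.replace(task, learner=cfg.compare_learner)
                cv_b = loocv_predict(itf.loc[expr.counts.index], expr.counts, task_b)
                diff, pval = compare_learners(cv, cv_b)
                table_b = pd.DataFrame({
                    "gene_id": cv_b.pcc.index, "pcc": cv_b.pcc.to_numpy(),
                    "n_spots": len(itf), "learner": cv_b.learner, "seed": cv_b.seed,
                })
                table = pd.concat([table, table_b], ignore_index=True)
                log.info("learner comparison: mean diff %.4f, paired p %.3g",
                         diff, pval)
            table.to_csv(predict_path, sep="\t", index=False,
                         float_format="%.10g")
            manifest.record("predict", key, [predict_path])
            log.info("predict: %d genes from %d ITFs", len(genes), len(itfs))
    return out_dir


def select_prediction_subsets(corr, n_genes: int, n_itfs: int):
    """Default subset choice: the genes with highest max |PCC|, then the
    ITFs with highest mean |PCC| against those genes."""
    abs_mat = corr.matrix.abs()
    genes = list(abs_mat.max(axis=1).sort_values(ascending=False, kind="stable")
                 .index[:n_genes])
    itfs = list(abs_mat.loc[genes].mean(axis=0)
                .sort_values(ascending=False, kind="stable").index[:n_itfs])
    return genes, itfs


def _write_synthetic_gmt(slide, gmt_path: Path, n_decoys: int, seed: int) -> None:
    """Planted term = the coupled genes; decoy terms are random draws."""
    from .studies import synthetic_gmt

    write_gmt(synthetic_gmt(slide, n_decoys=n_decoys, seed=seed), gmt_path)


def _read_corr(corr_path: Path):
    from .tag_analysis import CorrelationResult

    mat = pd.read_csv(corr_path, sep="\t", index_col="gene_id")
    return CorrelationResult(mat)


def _clip_k_range(k_range: tuple[int, int], corr) -> tuple[int, int]:
    n = min(len(corr.gene_ids), len(corr.itf_names))
    return (min(k_range[0], n), min(k_range[1], n))


def _write_assignments(sol, path: Path) -> None:
    df = pd.DataFrame({"item": sol.assignments.index,
                       "cluster": sol.assignments.to_numpy()})
    df.insert(0, "axis", sol.axis)
    df["k_chosen"] = sol.k_chosen
    df.to_csv(path, sep="\t", index=False)
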