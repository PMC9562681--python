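"""Synthetic slides with known topological ground truth.

Real slides pair each barcoded spot with the cell centroids found in its
image patch; here every spot draws a point pattern from a configurable
mixture (uniform Poisson, Matern-style clusters, rings, lattice), so the
slide carries known per-spot topology.  Two per-spot summaries drive gene
coupling:

* ``ring_count`` — the number of planted rings (an H1 quantity);
* ``mean_nn_dist`` — mean nearest-neighbor distance (an H0 quantity).

A coupled gene g draws counts from a negative binomial with log-mean
``alpha_g + sum_s beta_{g,s} * z_s``, where ``z_s`` is the per-slide
standardization of summary ``s``; uncoupled genes have all betas zero.
The negative binomial is parameterized by (mean mu, dispersion theta) with
variance ``mu + mu^2 / theta``, the standard stand-in for UMI counts.

Spots are laid out on a hex-like grid with pitch exactly one patch size,
so patches tile without overlap.  Point-cloud coordinates are patch-local
(row, col) pixels in ``[0, region)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stio import (
    ExpressionMatrix,
    SlideBundle,
    SpotPosition,
    write_expression,
    write_point_clouds,
    write_positions,
)

__all__ = [
    "PatternSpec",
    "GeneModel",
    "SyntheticSlide",
    "sample_pattern",
    "generate_slide",
    "write_slide",
    "default_pattern_mixture",
    "default_gene_models",
    "SUMMARY_NAMES",
]

SUMMARY_NAMES = ("ring_count", "mean_nn_dist")


@dataclass(frozen=True)
class PatternSpec:
    """One component of the per-spot point-pattern mixture.

    ``kind`` is one of poisson, matern_cluster, ring, lattice.  ``region``
    is the square side in pixels.  For poisson, either ``intensity``
    (points per px^2) or ``n_points``; for matern_cluster, ``n_clusters``
    parent clusters of radius ``cluster_radius``; for ring, ``n_rings``
    annuli of radius ``ring_radius`` and width ``ring_thickness`` with a
    ``background_frac`` of points scattered uniformly; for lattice, the
    largest k x k grid with at most ``n_points`` sites.
    """

    kind: str
    region: float = 350.0
    n_points: int | None = None
    intensity: float | None = None
    n_clusters: int = 4
    cluster_radius: float = 25.0
    n_rings: int = 1
    ring_radius: float = 55.0
    ring_thickness: float = 10.0
    background_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "matern_cluster", "ring", "lattice"):
            raise ValueError(f"unknown pattern kind: {self.kind!r}")
        if self.region <= 0:
            raise ValueError("region must be positive")
        if self.kind == "poisson":
            if self.intensity is None and self.n_points is None:
                raise ValueError("poisson needs intensity or n_points")
            if self.intensity is not None and self.intensity * self.region ** 2 < 1:
                raise ValueError("expected point count below 1")
        elif self.n_points is None or self.n_points < 1:
            raise ValueError(f"{self.kind} needs n_points >= 1")
        if self.kind == "ring":
            if self.n_rings < 1 or self.ring_radius <= 0 or self.ring_thickness <= 0:
                raise ValueError("ring parameters must be positive")
        if self.kind == "matern_cluster":
            if self.n_clusters < 1 or self.cluster_radius <= 0:
                raise ValueError("cluster parameters must be positive")

    @property
    def ring_count(self) -> int:
        return self.n_rings if self.kind == "ring" else 0


@dataclass(frozen=True)
class GeneModel:
    """Negative-binomial count model of one gene.

    ``alpha`` is the baseline log-mean; ``beta`` maps summary names to
    coupling coefficients (empty for uncoupled genes); ``dispersion`` is
    the NB theta (> 0, smaller = noisier).
    """

    gene_id: str
    alpha: float
    beta: dict[str, float] = field(default_factory=dict)
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        unknown = set(self.beta) - set(SUMMARY_NAMES)
        if unknown:
            raise ValueError(f"unknown summaries in beta: {sorted(unknown)}")

    @property
    def coupled(self) -> bool:
        return any(b != 0.0 for b in self.beta.values())


@dataclass
class SyntheticSlide:
    """A slide bundle plus its generating ground truth."""

    bundle: SlideBundle
    pattern_kinds: pd.Series  # spot_id -> mixture-component label
    summaries: pd.DataFrame   # spot_id x SUMMARY_NAMES
    gene_models: list[GeneModel]
    seed: int

    @property
    def coupled_genes(self) -> list[str]:
        return [g.gene_id for g in self.gene_models if g.coupled]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_pattern(spec: PatternSpec, rng_seed) -> np.ndarray:
    """Draw one point cloud; all points lie inside [0, region)^2."""
    rng = _as_rng(rng_seed)
    side = spec.region
    if spec.kind == "poisson":
        if spec.intensity is not None:
            n = int(rng.poisson(spec.intensity * side ** 2))
        else:
            n = int(spec.n_points)
        pts = rng.uniform(0.0, side, size=(n, 2))
    elif spec.kind == "lattice":
        k = max(1, int(np.floor(np.sqrt(spec.n_points))))
        spacing = side / (k + 1)
        grid = (np.arange(1, k + 1)) * spacing
        rr, cc = np.meshgrid(grid, grid, indexing="ij")
        pts = np.column_stack([rr.ravel(), cc.ravel()])
    elif spec.kind == "matern_cluster":
        n = int(spec.n_points)
        margin = spec.cluster_radius
        parents = rng.uniform(margin, side - margin, size=(spec.n_clusters, 2))
        assignment = rng.integers(0, spec.n_clusters, size=n)
        radii = spec.cluster_radius * np.sqrt(rng.uniform(0, 1, size=n))
        angles = rng.uniform(0, 2 * np.pi, size=n)
        pts = parents[assignment] + np.column_stack(
            [radii * np.cos(angles), radii * np.sin(angles)]
        )
    else:  # ring
        n = int(spec.n_points)
        n_bg = int(round(spec.background_frac * n))
        n_ring_total = n - n_bg
        margin = spec.ring_radius + spec.ring_thickness
        margin = min(margin, side / 2)
        centers = rng.uniform(margin, side - margin, size=(spec.n_rings, 2))
        per_ring = np.full(spec.n_rings, n_ring_total // spec.n_rings)
        per_ring[: n_ring_total % spec.n_rings] += 1
        chunks = []
        for c, m in zip(centers, per_ring):
            angles = rng.uniform(0, 2 * np.pi, size=m)
            radii = rng.uniform(
                spec.ring_radius - spec.ring_thickness / 2,
                spec.ring_radius + spec.ring_thickness / 2,
                size=m,
            )
            chunks.append(c + np.column_stack(
                [radii * np.cos(angles), radii * np.sin(angles)]
            ))
        chunks.append(rng.uniform(0.0, side, size=(n_bg, 2)))
        pts = np.concatenate(chunks, axis=0)
    eps = np.spacing(side)
    return np.clip(pts, 0.0, side - eps).reshape(-1, 2)


def mean_nn_dist(points: np.ndarray) -> float:
    """Mean nearest-neighbor distance; 0 for clouds below 2 points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return 0.0
    dists, _ = cKDTree(pts).query(pts, k=2)
    return float(dists[:, 1].mean())


def default_pattern_mixture(region: float = 350.0) -> list[tuple[PatternSpec, float]]:
    """Mixture used throughout the synthetic studies: sparse and dense
    uniform spots, clustered spots, and spots with 1-3 planted rings."""
    return [
        (PatternSpec("poisson", region=region, n_points=40), 0.15),
        (PatternSpec("poisson", region=region, n_points=90), 0.15),
        (PatternSpec("matern_cluster", region=region, n_points=70,
                     n_clusters=4, cluster_radius=25.0), 0.20),
        (PatternSpec("ring", region=region, n_points=45, n_rings=1), 0.20),
        (PatternSpec("ring", region=region, n_points=80, n_rings=2), 0.15),
        (PatternSpec("ring", region=region, n_points=115, n_rings=3), 0.15),
    ]


def default_gene_models(
    n_genes: int = 300,
    n_ring_coupled: int = 30,
    n_nn_coupled: int = 0,
    beta: float = 1.5,
    dispersion: float = 2.0,
    rng_seed=0,
) -> list[GeneModel]:
    """Gene panel: the first ``n_ring_coupled`` genes couple to ring count,
    the next ``n_nn_coupled`` to mean nearest-neighbor distance, the rest
    are uncoupled noise.  Baselines alpha_g ~ N(log 3, 0.8)."""
    rng = _as_rng(rng_seed)
    width = len(str(max(n_genes, 1)))
    models = []
    for i in range(n_genes):
        alpha = float(rng.normal(np.log(3.0), 0.8))
        if i < n_ring_coupled:
            b = {"ring_count": beta}
        elif i < n_ring_coupled + n_nn_coupled:
            b = {"mean_nn_dist": beta}
        else:
            b = {}
        models.append(GeneModel(
            gene_id=f"GENE{i + 1:0{width}d}", alpha=alpha, beta=b,
            dispersion=dispersion,
        ))
    return models


def _spot_grid(n_spots: int, pitch: float) -> list[SpotPosition]:
    """Hex-like layout with pitch exactly one patch size: odd rows shifted
    by half a pitch; vertical pitch one full patch so boxes cannot overlap."""
    ncols = int(np.ceil(np.sqrt(n_spots)))
    width = len(str(n_spots))
    positions = []
    for s in range(n_spots):
        r, c = divmod(s, ncols)
        positions.append(SpotPosition(
            spot_id=f"SPOT{s + 1:0{width}d}",
            in_tissue=True,
            array_row=r,
            array_col=c,
            pixel_row=pitch / 2 + r * pitch,
            pixel_col=pitch / 2 + c * pitch + (r % 2) * pitch / 2,
        ))
    return positions


def generate_slide(
    n_spots: int = 400,
    gene_models: list[GeneModel] | None = None,
    pattern_mixture: list[tuple[PatternSpec, float]] | None = None,
    rng_seed: int = 0,
    patch_size_px: int = 350,
) -> SyntheticSlide:
    """Simulate a whole slide: spot layout, per-spot point patterns,
    topological summaries, and NB gene counts coupled to the standardized
    summaries."""
    if n_spots < 2:
        raise ValueError("n_spots must be >= 2")
    if gene_models is None:
        gene_models = default_gene_models(rng_seed=rng_seed)
    if not gene_models:
        raise ValueError("need at least one gene model")
    if pattern_mixture is None:
        pattern_mixture = default_pattern_mixture(region=float(patch_size_px))
    specs = [s for s, _w in pattern_mixture]
    for s in specs:
        if s.region > patch_size_px:
            raise ValueError("pattern region exceeds patch size (spot pitch)")
    weights = np.asarray([w for _s, w in pattern_mixture], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("mixture weights must be non-negative and not all zero")
    weights = weights / weights.sum()

    rng = _as_rng(rng_seed)
    positions = _spot_grid(n_spots, float(patch_size_px))
    spot_ids = [p.spot_id for p in positions]

    draws = rng.choice(len(specs), size=n_spots, p=weights)
    clouds: dict[str, np.ndarray] = {}
    ring_counts = np.empty(n_spots)
    nn_dists = np.empty(n_spots)
    kinds = []
    for idx, spot_id in zip(draws, spot_ids):
        spec = specs[idx]
        pts = sample_pattern(spec, rng)
        clouds[spot_id] = pts
        i = len(kinds)
        ring_counts[i] = spec.ring_count
        nn_dists[i] = mean_nn_dist(pts)
        kinds.append(f"{spec.kind}:{spec.ring_count}" if spec.kind == "ring" else spec.kind)
    summaries = pd.DataFrame(
        {"ring_count": ring_counts, "mean_nn_dist": nn_dists}, index=spot_ids
    )

    # per-slide standardization of the summaries
    z = (summaries - summaries.mean()) / summaries.std(ddof=0).replace(0.0, 1.0)

    counts = np.empty((n_spots, len(gene_models)), dtype=np.int64)
    for j, gm in enumerate(gene_models):
        log_mu = np.full(n_spots, gm.alpha)
        for name, b in gm.beta.items():
            log_mu = log_mu + b * z[name].to_numpy()
        mu = np.exp(log_mu)
        theta = gm.dispersion
        counts[:, j] = rng.negative_binomial(theta, theta / (theta + mu))
    expr = ExpressionMatrix(pd.DataFrame(
        counts, index=spot_ids, columns=[g.gene_id for g in gene_models]
    ))
    bundle = SlideBundle(expression=expr, positions=positions, point_clouds=clouds)
    return SyntheticSlide(
        bundle=bundle,
        pattern_kinds=pd.Series(kinds, index=spot_ids, name="pattern"),
        summaries=summaries,
        gene_models=gene_models,
        seed=int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else -1,
    )


def write_slide(slide: SyntheticSlide, out_dir: str | Path) -> dict[str, Path]:
    """Write the full slide: MTX triplet, positions CSV, point-cloud TSV,
    and ground-truth TSVs (gene models and per-spot summaries)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_expression(slide.bundle.expression, out_dir)
    paths["positions"] = write_positions(
        slide.bundle.positions, out_dir / "tissue_positions.csv"
    )
    paths["point_clouds"] = write_point_clouds(
        slide.bundle.point_clouds, out_dir / "point_clouds.tsv"
    )
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in slide.gene_models],
        "coupled": [int(g.coupled) for g in slide.gene_models],
        "alpha": [g.alpha for g in slide.gene_models],
        "beta_ring_count": [g.beta.get("ring_count", 0.0) for g in slide.gene_models],
        "beta_mean_nn_dist": [g.beta.get("mean_nn_dist", 0.0) for g in slide.gene_models],
        "dispersion": [g.dispersion for g in slide.gene_models],
    })
    paths["ground_truth"] = out_dir / "ground_truth_genes.tsv"
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    paths["summaries"] = out_dir / "ground_truth_spots.tsv"
    spot_truth = slide.summaries.copy()
    spot_truth.insert(0, "pattern", slide.pattern_kinds)
    spot_truth.to_csv(paths["summaries"], sep="\t", index_label="spot_id")
    return paths
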