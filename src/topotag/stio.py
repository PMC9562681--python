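"""Readers and writers for the on-disk formats used throughout the pipeline.

Conventions used everywhere in this package:

* coordinates are 0-based ``(row, col)`` pairs in full-resolution pixel units;
* the count matrix is stored on disk genes x spots (10x MatrixMarket
  convention) but held in memory spots x genes;
* ``barcodes.tsv`` / ``features.tsv`` may be gzipped, detected by extension.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SpotPosition",
    "SlideBundle",
    "PipelineConfig",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_positions",
    "write_positions",
    "read_point_clouds",
    "write_point_clouds",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared format."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class ExpressionMatrix:
    """Spots x genes UMI count matrix with named axes.

    ``counts`` is a dense DataFrame (spot barcodes as index, gene ids as
    columns); slides at the scale this package targets fit comfortably in
    memory dense.
    """

    counts: pd.DataFrame

    @property
    def spot_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def log1p(self) -> pd.DataFrame:
        """Log-transformed view, ``log(1 + x)`` elementwise."""
        return np.log1p(self.counts)


@dataclass(frozen=True)
class SpotPosition:
    """One row of a Visium ``tissue_positions`` table."""

    spot_id: str
    in_tissue: bool
    array_row: int
    array_col: int
    pixel_row: float
    pixel_col: float


@dataclass
class SlideBundle:
    """Everything known about one slide: expression, spot geometry, and
    (optionally) per-spot cell point clouds and/or a raster image."""

    expression: ExpressionMatrix
    positions: list[SpotPosition]
    point_clouds: dict[str, np.ndarray] | None = None
    image: np.ndarray | None = None

    def __post_init__(self) -> None:
        expr_ids = set(self.expression.spot_ids)
        pos_ids = [p.spot_id for p in self.positions]
        if len(pos_ids) != len(set(pos_ids)):
            raise FormatError("duplicate spot_ids in positions table")
        if expr_ids != set(pos_ids):
            missing = expr_ids.symmetric_difference(pos_ids)
            raise FormatError(
                f"spot_ids of expression and positions disagree: {sorted(missing)[:5]} ..."
            )
        if self.point_clouds is not None and set(self.point_clouds) != expr_ids:
            missing = expr_ids.symmetric_difference(self.point_clouds)
            raise FormatError(
                f"spot_ids of point clouds disagree with expression: {sorted(missing)[:5]} ..."
            )

    def position_of(self, spot_id: str) -> SpotPosition:
        for p in self.positions:
            if p.spot_id == spot_id:
                return p
        raise KeyError(spot_id)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline in one place.

    Defaults mirror the published analysis: 350 px patches, genes with at
    most 25% zero reads, top 150 most-variable genes, k-means baseline of
    10 clusters, significance level 0.05.
    """

    patch_size_px: int = 350
    max_zero_frac: float = 0.25
    top_n_genes: int = 150
    k_baseline: int = 10
    k_range: tuple[int, int] = (2, 12)
    alpha: float = 0.05
    n_birth_bins: int = 35
    n_pers_bins: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_zero_frac <= 1.0:
            raise ValueError("max_zero_frac must be in [0, 1]")
        if self.top_n_genes < 1:
            raise ValueError("top_n_genes must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")

    @property
    def patch_diagonal(self) -> float:
        return float(self.patch_size_px) * np.sqrt(2.0)


# ---------------------------------------------------------------------------
# expression (MTX triplet)
# ---------------------------------------------------------------------------

def read_expression(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket triplet into a spots x genes matrix.

    The MTX file is genes x spots on disk (10x convention); the returned
    matrix is transposed to spots x genes.
    """
    mat = scipy.io.mmread(str(mtx_path))
    mat = scipy.sparse.coo_matrix(mat)
    with _open_text(barcodes_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(features_path) as fh:
        features = [line.strip().split("\t")[0] for line in fh if line.strip()]
    n_genes, n_spots = mat.shape
    if n_genes != len(features):
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix has {n_genes} rows"
        )
    if n_spots != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {n_spots} columns"
        )
    dense = np.asarray(mat.todense()).T  # spots x genes
    return ExpressionMatrix(pd.DataFrame(dense, index=barcodes, columns=features))


def write_expression(expr: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` (genes x spots on disk)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "matrix.mtx",
        "barcodes": out_dir / "barcodes.tsv",
        "features": out_dir / "features.tsv",
    }
    sparse = scipy.sparse.coo_matrix(expr.counts.to_numpy().T)
    scipy.io.mmwrite(str(paths["mtx"]), sparse)
    paths["barcodes"].write_text("".join(f"{b}\n" for b in expr.spot_ids))
    paths["features"].write_text("".join(f"{g}\n" for g in expr.gene_ids))
    return paths


# ---------------------------------------------------------------------------
# spot positions (tissue_positions CSV, headerless v1 or headered v2)
# ---------------------------------------------------------------------------

_POSITIONS_HEADER = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_positions(csv_path: str | Path) -> list[SpotPosition]:
    """Read a ``tissue_positions`` CSV; both the headerless and the
    header-bearing Visium dialects are auto-detected."""
    positions: list[SpotPosition] = []
    with _open_text(csv_path) as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0] and not rows[0][1].strip().lstrip("-").isdigit():
        rows = rows[1:]  # header row
    for i, row in enumerate(rows):
        if not row:
            continue
        if len(row) != 6:
            raise FormatError(f"{csv_path} row {i + 1}: expected 6 columns, got {len(row)}")
        try:
            pos = SpotPosition(
                spot_id=row[0].strip(),
                in_tissue=bool(int(row[1])),
                array_row=int(row[2]),
                array_col=int(row[3]),
                pixel_row=float(row[4]),
                pixel_col=float(row[5]),
            )
        except ValueError as exc:
            raise FormatError(f"{csv_path} row {i + 1}: {exc}") from exc
        if pos.pixel_row < 0 or pos.pixel_col < 0:
            raise FormatError(f"{csv_path} row {i + 1}: negative pixel coordinate")
        positions.append(pos)
    if not positions:
        log.warning("%s: no spot positions found", csv_path)
    return positions


def write_positions(
    positions: list[SpotPosition], csv_path: str | Path, header: bool = True
) -> Path:
    csv_path = Path(csv_path)
    with open(csv_path, "wt", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow(_POSITIONS_HEADER)
        for p in positions:
            writer.writerow(
                [p.spot_id, int(p.in_tissue), p.array_row, p.array_col,
                 _fmt_px(p.pixel_row), _fmt_px(p.pixel_col)]
            )
    return csv_path


def _fmt_px(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# point clouds (TSV: spot_id, x, y) -- x = pixel col, y = pixel row, both
# relative to the spot's patch origin
# ---------------------------------------------------------------------------

def read_point_clouds(tsv_path: str | Path) -> dict[str, np.ndarray]:
    """Read per-spot cell centroids; returns spot_id -> (n, 2) array of
    (row, col) pixel coordinates."""
    by_spot: dict[str, list[tuple[float, float]]] = {}
    with _open_text(tsv_path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if i == 0 and parts[0] == "spot_id":
                continue
            if len(parts) != 3:
                raise FormatError(f"{tsv_path} line {i + 1}: expected 3 columns")
            spot_id, x, y = parts
            try:
                col, row = float(x), float(y)
            except ValueError as exc:
                raise FormatError(f"{tsv_path} line {i + 1}: {exc}") from exc
            by_spot.setdefault(spot_id, []).append((row, col))
    return {s: np.asarray(pts, dtype=float) for s, pts in by_spot.items()}


def write_point_clouds(clouds: dict[str, np.ndarray], tsv_path: str | Path) -> Path:
    tsv_path = Path(tsv_path)
    with open(tsv_path, "wt") as fh:
        fh.write("spot_id\tx\ty\n")
        for spot_id in clouds:
            pts = np.atleast_2d(np.asarray(clouds[spot_id], dtype=float))
            for row, col in pts.reshape(-1, 2):
                fh.write(f"{spot_id}\t{float(col)!r}\t{float(row)!r}\n")
    return tsv_path


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into term_id -> gene set.

    Lines with fewer than 3 tab-separated fields are skipped with a warning;
    duplicate genes within a term are deduplicated; term order is preserved
    (dicts are insertion-ordered).
    """
    terms: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                log.warning("%s line %d: fewer than 3 fields, skipped", path, i + 1)
                continue
            term_id = parts[0]
            genes = {g for g in parts[2:] if g}
            terms[term_id] = genes
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    with open(path, "wt") as fh:
        for term_id, genes in terms.items():
            desc = (descriptions or {}).get(term_id, "na")
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")
    return path
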