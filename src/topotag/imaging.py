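"""Patch tiling, synthetic patch rendering, and nucleus-centroid detection.

The pipeline normally starts from per-spot point clouds; when only an
image is available, patches are cut around each spot and cell centroids
are detected by a deliberately simple scheme — global threshold on a
hematoxylin-like optical-density channel followed by connected-component
centroids.  Detection quality on real stains is not a goal; the contract
is centroid recovery on rendered patches.

Patches are axis-aligned squares centered on each spot's pixel position,
half-open ``[row0, row1) x [col0, col1)``, clipped at the image border.
Two patches may never overlap: spot pitch below the patch size is an
error, not a silent crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hed
from skimage.draw import disk
from skimage.measure import label, regionprops

from .stio import SpotPosition

__all__ = ["PatchBox", "tile_patches", "render_patch", "detect_nuclei"]


@dataclass(frozen=True)
class PatchBox:
    """Half-open pixel bounds of one spot's patch."""

    spot_id: str
    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    def overlaps(self, other: "PatchBox") -> bool:
        return (self.row0 < other.row1 and other.row0 < self.row1
                and self.col0 < other.col1 and other.col0 < self.col1)


def tile_patches(
    positions: list[SpotPosition],
    image_dims: tuple[int, int],
    patch_size_px: int,
) -> list[PatchBox]:
    """Boxes of ``patch_size_px`` centered on each in-tissue spot, clipped
    to the image; raises if any two boxes overlap (spot pitch below the
    patch size) or a spot lies outside the image."""
    if patch_size_px <= 0:
        raise ValueError("patch_size_px must be positive")
    nrow, ncol = image_dims
    half = patch_size_px / 2.0
    boxes = []
    for p in positions:
        if not p.in_tissue:
            continue
        if not (0 <= p.pixel_row < nrow and 0 <= p.pixel_col < ncol):
            raise ValueError(f"spot {p.spot_id} lies outside the image")
        row0 = int(round(p.pixel_row - half))
        col0 = int(round(p.pixel_col - half))
        box = PatchBox(
            spot_id=p.spot_id,
            row0=max(0, row0),
            col0=max(0, col0),
            row1=min(nrow, row0 + patch_size_px),
            col1=min(ncol, col0 + patch_size_px),
        )
        boxes.append(box)
    # sweep over boxes sorted by row0: only candidates whose row ranges
    # intersect can overlap, keeping the check near-linear on grids
    order = sorted(boxes, key=lambda b: (b.row0, b.col0))
    for i, bi in enumerate(order):
        for bj in order[i + 1:]:
            if bj.row0 >= bi.row1:
                break
            if bi.overlaps(bj):
                raise ValueError(
                    f"patches of spots {bi.spot_id} and {bj.spot_id} "
                    f"overlap: spot pitch is below the patch size"
                )
    return boxes


def render_patch(points, patch_size_px: int, cell_radius_px: float) -> np.ndarray:
    """Render cell centroids as dark disks on a light background.

    Returns a float grayscale raster in [0, 1] (background 1.0, nuclei
    0.0), no anti-aliasing; the fixture counterpart of detect_nuclei.
    """
    if cell_radius_px <= 0:
        raise ValueError("cell_radius_px must be positive")
    img = np.ones((patch_size_px, patch_size_px), dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) and (pts.min() < 0 or pts.max() >= patch_size_px):
        raise ValueError("points must lie within the patch")
    for row, col in pts:
        rr, cc = disk((row, col), cell_radius_px, shape=img.shape)
        img[rr, cc] = 0.0
    return img


def _hematoxylin_od(raster: np.ndarray) -> np.ndarray:
    """Darkness channel used for detection: 1 - intensity for grayscale,
    the hematoxylin optical-density channel for RGB."""
    if raster.ndim == 2:
        return 1.0 - raster.astype(float)
    if raster.ndim == 3 and raster.shape[2] == 3:
        rgb = raster.astype(float)
        if rgb.max() > 1.0:
            rgb = rgb / 255.0
        hed = rgb2hed(rgb)
        return hed[..., 0]
    raise ValueError("raster must be 2-D grayscale or 3-channel RGB")


def detect_nuclei(raster: np.ndarray, threshold: float = 0.5,
                  min_area_px: int = 1) -> np.ndarray:
    """Centroids of connected dark components with area >= min_area_px.

    Returns an (n, 2) array of (row, col) centroids; an empty or uniform
    raster yields an empty cloud.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        return np.empty((0, 2))
    od = _hematoxylin_od(raster)
    mask = od > threshold
    labeled = label(mask, connectivity=2)
    centroids = [
        r.centroid for r in regionprops(labeled) if r.area >= min_area_px
    ]
    if not centroids:
        return np.empty((0, 2))
    out = np.asarray(centroids, dtype=float)
    return out[np.lexsort((out[:, 1], out[:, 0]))]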