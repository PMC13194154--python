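"""Patch-grid construction and stromal TIL counting.

A slide is tiled with non-overlapping square patches (default 100 μm side)
anchored at the minimum corner of the tissue bounding box.  Detections whose
box center lies in stroma — inside a tissue contour and outside every tumor
parenchyma polygon — are counted into the unique patch containing the center
(half-open square convention).  Per-patch counts ``Num`` are normalized by
the slide maximum ``NumMax`` to the relative lymphocyte density
``a = Num / NumMax`` in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.ops import unary_union

from .annotations import SlideAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridConfig:
    """Patch-grid parameters.

    patch_size_um
        Side of the square patches in microns; window equals step, so the
        grid is a partition of the tissue bounding box.
    min_tissue_fraction
        Optional QC filter: when set, patches whose tissue coverage falls
        below this fraction are marked invalid regardless of TIL content.
        Off by default (scoring uses all TIL-containing patches).
    """

    patch_size_um: float = 100.0
    min_tissue_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.patch_size_um > 0:
            raise ValueError("patch_size_um must be positive")
        if self.min_tissue_fraction is not None and not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must lie in [0, 1]")


@dataclass
class PatchRecord:
    """One grid cell: location, TIL count, normalized density and flags."""

    row: int
    col: int
    x0_um: float
    y0_um: float
    num_tils: int = 0
    a: float | None = None
    is_valid: bool = False
    is_high_attention: bool = False
    tissue_fraction: float | None = None


@dataclass
class SlideGrid:
    """The full patch grid of one slide plus slide-level aggregates."""

    slide_id: str
    config: GridConfig
    n_rows: int
    n_cols: int
    origin_um: tuple[float, float]
    patches: list[PatchRecord] = field(default_factory=list)
    num_max: int = 0
    degenerate: bool = False

    def counts_array(self) -> np.ndarray:
        """Patch counts as an (n_rows, n_cols) integer array."""
        arr = np.zeros((self.n_rows, self.n_cols), dtype=np.int64)
        for p in self.patches:
            arr[p.row, p.col] = p.num_tils
        return arr

    def density_array(self) -> np.ndarray:
        """Normalized densities ``a`` as an (n_rows, n_cols) float array."""
        arr = np.zeros((self.n_rows, self.n_cols), dtype=float)
        for p in self.patches:
            arr[p.row, p.col] = 0.0 if p.a is None else p.a
        return arr

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "row": [p.row for p in self.patches],
                "col": [p.col for p in self.patches],
                "x0_um": [p.x0_um for p in self.patches],
                "y0_um": [p.y0_um for p in self.patches],
                "num_tils": [p.num_tils for p in self.patches],
                "a": [p.a for p in self.patches],
                "is_valid": [p.is_valid for p in self.patches],
                "is_high_attention": [p.is_high_attention for p in self.patches],
            }
        )


def _n_cells(extent: float, step: float) -> int:
    # tolerance keeps exact multiples from spilling into a spurious extra cell
    return max(1, math.ceil(extent / step - 1e-9))


def build_patch_grid(annotation: SlideAnnotation, config: GridConfig | None = None) -> SlideGrid:
    """Tile the tissue bounding box with half-open square patches.

    Patches are ``[x0, x0 + s) x [y0, y0 + s)`` in micron space, anchored at
    the minimum corner of the joint bounding box of all tissue polygons.
    Partial patches at the far edges are retained.
    """
    config = config or GridConfig()
    if not annotation.tissue_polygons:
        raise ValueError("annotation has no tissue polygons")
    s = config.patch_size_um
    mpp = annotation.mpp
    xs0, ys0, xs1, ys1 = unary_union(annotation.tissue_polygons).bounds
    x0, y0, x1, y1 = xs0 * mpp, ys0 * mpp, xs1 * mpp, ys1 * mpp
    n_cols = _n_cells(x1 - x0, s)
    n_rows = _n_cells(y1 - y0, s)
    patches = [
        PatchRecord(row=r, col=c, x0_um=x0 + c * s, y0_um=y0 + r * s)
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return SlideGrid(
        slide_id=annotation.slide_id,
        config=config,
        n_rows=n_rows,
        n_cols=n_cols,
        origin_um=(x0, y0),
        patches=patches,
    )


def stromal_detection_mask(annotation: SlideAnnotation) -> np.ndarray:
    """Boolean mask over detections: center in tissue and outside all tumor.

    Uses the even-odd rule with boundary points counting as inside (for both
    tissue and tumor, so a center on a tumor boundary is excluded from
    stroma).
    """
    centers = np.asarray([d.center for d in annotation.detections], dtype=float)
    if centers.size == 0:
        return np.zeros(0, dtype=bool)
    tissue = unary_union(annotation.tissue_polygons) if annotation.tissue_polygons else None
    in_tissue = (
        shapely.intersects_xy(tissue, centers[:, 0], centers[:, 1])
        if tissue is not None
        else np.zeros(len(centers), dtype=bool)
    )
    if annotation.tumor_polygons:
        tumor = unary_union(annotation.tumor_polygons)
        in_tumor = shapely.intersects_xy(tumor, centers[:, 0], centers[:, 1])
    else:
        in_tumor = np.zeros(len(centers), dtype=bool)
    return in_tissue & ~in_tumor


def count_tils(grid: SlideGrid, annotation: SlideAnnotation) -> SlideGrid:
    """Count stromal detections into patches; set ``num_max`` and validity.

    Each counted detection increments exactly one patch — the half-open
    square containing its box center.  A center exactly on the far edge of
    the grid (measure zero) is clamped into the last patch.  ``is_valid`` is
    true exactly for patches holding at least one counted TIL (and meeting
    the optional tissue-fraction QC when enabled).
    """
    if grid.slide_id != annotation.slide_id:
        raise ValueError(f"grid built for {grid.slide_id!r}, annotation is {annotation.slide_id!r}")
    s = grid.config.patch_size_um
    x0, y0 = grid.origin_um
    mask = stromal_detection_mask(annotation)
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int64)
    if mask.any():
        centers = np.asarray([d.center for d in annotation.detections], dtype=float)[mask]
        centers_um = centers * annotation.mpp
        cols = np.floor((centers_um[:, 0] - x0) / s).astype(np.int64)
        rows = np.floor((centers_um[:, 1] - y0) / s).astype(np.int64)
        edge = (cols == grid.n_cols) & (centers_um[:, 0] <= x0 + grid.n_cols * s + 1e-9)
        cols[edge] = grid.n_cols - 1
        edge = (rows == grid.n_rows) & (centers_um[:, 1] <= y0 + grid.n_rows * s + 1e-9)
        rows[edge] = grid.n_rows - 1
        inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
        if not inside.all():
            logger.warning(
                "%s: %d stromal detections fall outside the patch grid",
                grid.slide_id,
                int((~inside).sum()),
            )
        np.add.at(counts, (rows[inside], cols[inside]), 1)

    qc = grid.config.min_tissue_fraction
    if qc is not None:
        tissue_frac = _patch_tissue_fractions(grid, annotation)
    for p in grid.patches:
        p.num_tils = int(counts[p.row, p.col])
        p.is_valid = p.num_tils >= 1
        if qc is not None:
            p.tissue_fraction = tissue_frac[p.row, p.col]
            p.is_valid = p.is_valid and p.tissue_fraction >= qc
    grid.num_max = int(counts.max()) if grid.patches else 0
    grid.degenerate = grid.num_max == 0
    return grid


def _patch_tissue_fractions(grid: SlideGrid, annotation: SlideAnnotation) -> np.ndarray:
    tissue = unary_union(annotation.tissue_polygons)
    s = grid.config.patch_size_um
    x0, y0 = grid.origin_um
    mpp = annotation.mpp
    frac = np.zeros((grid.n_rows, grid.n_cols), dtype=float)
    for p in grid.patches:
        box = shapely.box(
            p.x0_um / mpp, p.y0_um / mpp, (p.x0_um + s) / mpp, (p.y0_um + s) / mpp
        )
        frac[p.row, p.col] = tissue.intersection(box).area / box.area
    return frac


def normalize_density(grid: SlideGrid) -> SlideGrid:
    """Set ``a = num_tils / num_max`` for every patch.

    A slide with no counted TILs at all (``num_max == 0``) is degenerate:
    every ``a`` is set to 0 and the slide-level flag raised with a loud
    warning; downstream scoring assigns it Score 0 / Immunity_L.
    """
    if grid.num_max > 0:
        for p in grid.patches:
            p.a = p.num_tils / grid.num_max
    else:
        grid.degenerate = True
        logger.warning("%s: degenerate slide (no stromal TILs counted); all a=0", grid.slide_id)
        for p in grid.patches:
            p.a = 0.0
    return grid


def quantify_slide(annotation: SlideAnnotation, config: GridConfig | None = None) -> SlideGrid:
    """Convenience: grid construction, counting and normalization in one call."""
    grid = build_patch_grid(annotation, config)
    count_tils(grid, annotation)
    return normalize_density(grid)
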