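"""Interpolated TIL spatial-distribution heatmaps.

Per-patch normalized densities are bilinearly interpolated between patch
centers onto a fine grid and rendered with a fixed diverging colormap:
blue at a=0 (sparse or absent infiltration) through red at a=1 (dense
infiltration), so colors are comparable across slides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SlideGrid

_CMAP_COLORS = ["#2c7bb6", "#ffffbf", "#d7191c"]  # blue -> pale -> red


@dataclass(frozen=True)
class HeatmapConfig:
    """Rendering parameters for density heatmaps."""

    upsample_factor: int = 8
    mask_outside_tissue: bool = True
    overlay_alpha: float = 0.6

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if not 0.0 <= self.overlay_alpha <= 1.0:
            raise ValueError("overlay_alpha must lie in [0, 1]")


def _bilinear(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear lookup at fractional (row, col) node indices.

    Coordinates are clamped to the node hull, giving constant extension in
    the outer half-patch band; works for single-row/column grids.
    """
    n_r, n_c = values.shape
    r = np.clip(rows, 0.0, n_r - 1.0)
    c = np.clip(cols, 0.0, n_c - 1.0)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, n_r - 1)
    c1 = np.minimum(c0 + 1, n_c - 1)
    fr = r - r0
    fc = c - c0
    top = values[r0, c0] * (1 - fc) + values[r0, c1] * fc
    bot = values[r1, c0] * (1 - fc) + values[r1, c1] * fc
    return top * (1 - fr) + bot * fr


def sample_surface(grid: SlideGrid, points_um: np.ndarray) -> np.ndarray:
    """Evaluate the bilinear density interpolant at micron coordinates.

    Nodes sit at patch centers; the interpolant passes exactly through the
    per-patch a-values there.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    s = grid.config.patch_size_um
    x0, y0 = grid.origin_um
    cols = (pts[:, 0] - x0) / s - 0.5
    rows = (pts[:, 1] - y0) / s - 0.5
    return _bilinear(grid.density_array(), rows, cols)


def interpolate_density_surface(
    grid: SlideGrid,
    config: HeatmapConfig | None = None,
    annotation=None,
) -> np.ma.MaskedArray:
    """Bilinear density surface on a fine grid (upsample_factor² cells/patch).

    Values are clipped to [0, 1]; by bilinear convexity they never leave
    the [min(a), max(a)] range of the inputs.  When ``annotation`` is given
    and masking is enabled, fine cells whose centers fall outside the
    tissue polygons are masked.
    """
    config = config or HeatmapConfig()
    if not grid.patches:
        raise ValueError("grid has no patches")
    f = config.upsample_factor
    s = grid.config.patch_size_um
    x0, y0 = grid.origin_um
    h, w = grid.n_rows * f, grid.n_cols * f
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    xs = x0 + (jj + 0.5) * s / f
    ys = y0 + (ii + 0.5) * s / f
    vals = sample_surface(grid, np.column_stack([xs.ravel(), ys.ravel()])).reshape(h, w)
    vals = np.clip(vals, 0.0, 1.0)

    mask = np.zeros_like(vals, dtype=bool)
    if config.mask_outside_tissue and annotation is not None and annotation.tissue_polygons:
        import shapely
        from shapely.ops import unary_union

        tissue = unary_union(annotation.tissue_polygons)
        inside = shapely.intersects_xy(
            tissue, xs.ravel() / annotation.mpp, ys.ravel() / annotation.mpp
        ).reshape(h, w)
        mask = ~inside
    return np.ma.MaskedArray(vals, mask=mask)


def render_heatmap(
    surface: np.ndarray | np.ma.MaskedArray,
    path,
    config: HeatmapConfig | None = None,
    background: np.ndarray | None = None,
) -> None:
    """Render a density surface to PNG (blue at 0, red at 1, with colorbar).

    Rendering is a pure function of (surface, config, background): repeated
    calls write byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    config = config or HeatmapConfig()
    cmap = LinearSegmentedColormap.from_list("til_density", _CMAP_COLORS)
    cmap.set_bad(alpha=0.0)

    fig, ax = plt.subplots(figsize=(6, 5), dpi=150)
    if background is not None:
        bh, bw = background.shape[:2]
        sh, sw = surface.shape
        if (bh, bw) != (sh, sw):
            raise ValueError(f"background shape {(bh, bw)} != surface shape {(sh, sw)}")
        ax.imshow(background, interpolation="nearest")
        im = ax.imshow(surface, cmap=cmap, vmin=0.0, vmax=1.0, alpha=config.overlay_alpha, interpolation="nearest")
    else:
        im = ax.imshow(surface, cmap=cmap, vmin=0.0, vmax=1.0, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="normalized TIL density a")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", metadata={"Software": "tilscore"})
    plt.close(fig)
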