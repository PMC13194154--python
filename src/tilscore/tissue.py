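"""Classical tissue-contour segmentation and mask-overlap metrics.

The segmentation pipeline is non-learned image processing: downsample to
the scale of a 2.5x objective, Roberts gradient + Otsu binarization unioned
with Canny(30, 120) edges for weak boundaries, two elliptical 3x3 closings,
border flood-fill of internal holes, and speckle suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import feature, filters, measure, morphology, transform
from skimage.color import rgb2gray

# pixel pitch of a 2.5x objective (40x scans at ~0.25 um/px)
MPP_AT_2_5X = 4.0


@dataclass(frozen=True)
class TissueMaskConfig:
    """Parameters of the classical tissue-contour pipeline."""

    target_mpp: float = MPP_AT_2_5X
    gaussian_sigma: float = 1.5
    median_kernel: int = 3
    canny_low: float = 30.0
    canny_high: float = 120.0
    closing_kernel: int = 3
    closing_iterations: int = 2
    min_component_frac: float = 0.001  # speckle filter, fraction of frame area

    def __post_init__(self) -> None:
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be below canny_high")
        if self.median_kernel % 2 == 0 or self.closing_kernel % 2 == 0:
            raise ValueError("kernels must be odd-sized")
        if self.closing_iterations < 1:
            raise ValueError("closing_iterations must be >= 1")


def preprocess_image(image: np.ndarray, missing_mask: np.ndarray | None = None) -> np.ndarray:
    """Denoise (Gaussian sigma 1.5 + 3x3 median) and fill missing pixels.

    ``missing_mask`` flags pixels to reconstruct by bilinear interpolation
    from valid neighbors before filtering.  Output keeps the input dtype
    range and dimensions.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if missing_mask is not None:
        missing_mask = np.asarray(missing_mask, dtype=bool)
        if missing_mask.all():
            raise ValueError("all pixels flagged missing")
        if missing_mask.any():
            img = _fill_missing(img, missing_mask)
    # median first so impulse noise cannot be smeared by the gaussian
    size = (3, 3, 1) if img.ndim == 3 else (3, 3)
    img = ndimage.median_filter(img, size=size)
    sigma = (1.5, 1.5, 0) if img.ndim == 3 else 1.5
    img = ndimage.gaussian_filter(img, sigma=sigma)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.clip(np.rint(img), 0, 255).astype(np.asarray(image).dtype)
    return img


def _fill_missing(img: np.ndarray, missing: np.ndarray) -> np.ndarray:
    from scipy.interpolate import griddata

    out = img.copy()
    yy, xx = np.nonzero(~missing)
    my, mx = np.nonzero(missing)
    channels = img[..., None] if img.ndim == 2 else img
    outc = out[..., None] if out.ndim == 2 else out
    for c in range(channels.shape[-1]):
        vals = channels[yy, xx, c]
        filled = griddata((yy, xx), vals, (my, mx), method="linear")
        bad = np.isnan(filled)
        if bad.any():  # outside convex hull of valid pixels
            filled[bad] = griddata((yy, xx), vals, (my[bad], mx[bad]), method="nearest")
        outc[my, mx, c] = filled
    return out


def segment_tissue(
    image: np.ndarray,
    config: TissueMaskConfig | None = None,
    mpp: float | None = None,
) -> tuple[np.ndarray, list[Polygon]]:
    """Segment tissue from a bright-field raster.

    Returns the binary mask at input resolution and the contour polygons in
    input pixel coordinates.  ``mpp`` (microns/pixel of the input) drives
    the downsampling to the 2.5x-equivalent working scale; when absent a
    fixed 1/16 downsample is used.
    """
    config = config or TissueMaskConfig()
    img = np.asarray(image)
    if img.ndim not in (2, 3):
        raise ValueError("expected a 2-D grayscale or RGB image")
    gray = rgb2gray(img) if img.ndim == 3 else img.astype(np.float64)
    if gray.max() > 1.0:
        gray = gray / 255.0

    scale = (mpp / config.target_mpp) if mpp is not None else 1.0 / 16.0
    scale = min(scale, 1.0)
    if scale < 1.0:
        work = transform.rescale(gray, scale, anti_aliasing=True)
    else:
        work = gray
    if min(work.shape) < config.closing_kernel:
        raise ValueError("image too small for the configured kernels")

    grad = filters.roberts(work)
    if grad.max() > grad.min():
        edges = grad > filters.threshold_otsu(grad)
    else:
        edges = np.zeros_like(work, dtype=bool)
    # Canny thresholds are calibrated on the 0-255 intensity scale
    edges |= feature.canny(
        work * 255.0,
        low_threshold=config.canny_low,
        high_threshold=config.canny_high,
        use_quantiles=False,
    )

    footprint = morphology.disk(config.closing_kernel // 2)
    mask = edges
    for _ in range(config.closing_iterations):
        mask = ndimage.binary_closing(mask, structure=footprint)
    mask = ndimage.binary_fill_holes(mask)
    min_area = max(1, int(config.min_component_frac * mask.size))
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area) + 1
        mask = np.isin(labels, keep)

    contours = measure.find_contours(mask.astype(float), 0.5)
    polygons = []
    for c in contours:
        if len(c) < 4:
            continue
        # find_contours yields (row, col); convert to (x, y) at input scale
        poly = Polygon(np.column_stack([c[:, 1], c[:, 0]]) / scale)
        if poly.is_valid and poly.area > 0:
            polygons.append(poly)

    if scale < 1.0:
        full = transform.resize(mask.astype(float), gray.shape, order=0) > 0.5
    else:
        full = mask
    return full, polygons


def mask_overlap_metrics(mask_pred: np.ndarray, mask_true: np.ndarray) -> dict[str, float]:
    """Dice, precision and recall between two equal-shaped binary masks.

    Empty-vs-empty is defined as perfect agreement (all metrics 1.0); a
    metric whose denominator alone is empty is 0.0.
    """
    a = np.asarray(mask_pred, dtype=bool)
    b = np.asarray(mask_true, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return {"dice": 1.0, "precision": 1.0, "recall": 1.0}
    return {
        "dice": 2.0 * inter / (na + nb),
        "precision": inter / na if na else 0.0,
        "recall": inter / nb if nb else 0.0,
    }
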