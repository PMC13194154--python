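"""Synthetic annotated slides and IHC count tables.

Slides are simulated in micron space as a tissue polygon (rounded rectangle
by default) containing tumor-parenchyma blobs; TIL detections are placed in
the stroma (tissue minus tumor) by the superposition of

* a homogeneous Poisson process at ``background_intensity`` cells/mm² of
  stroma, and
* a Thomas cluster process: Poisson parents at ``cluster_parent_intensity``
  parents/mm² of tissue, each spawning a Poisson(``cluster_mean_size``)
  number of offspring displaced by an isotropic Gaussian with SD
  ``cluster_sd_um``; offspring landing outside stroma are rejected.

Low-immunity slides are dominated by the sparse homogeneous background with
rare small foci; high-immunity slides add many dense clusters, yielding the
bimodal patch-density pattern the subtype rule exploits.  All randomness
flows from explicit seeds; per-slide seeds derive deterministically from the
cohort seed and slide index.

The IHC simulator draws 10 field counts per case and marker from truncated
normals (or negative binomials) whose group means and SDs default to the
magnitudes observed in immunostained lung-adenocarcinoma cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .annotations import SlideAnnotation, TILDetection

UM2_PER_MM2 = 1e6

# lymphocyte nucleus is ~8 um across; detections are emitted as boxes of
# this side length centred on the simulated points
DETECTION_BOX_UM = 8.0


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry and point-process parameters of one synthetic slide."""

    slide_width_um: float = 3000.0
    slide_height_um: float = 3000.0
    mpp: float = 0.25
    tissue_shape: Polygon | None = None  # default: rounded rectangle inset from bounds
    tumor_fraction: float = 0.3
    background_intensity: float = 60.0  # cells/mm^2 of stroma
    cluster_parent_intensity: float = 0.0  # parents/mm^2 of tissue
    cluster_mean_size: float = 0.0  # mean offspring per parent
    cluster_sd_um: float = 50.0  # offspring displacement SD
    detection_box_um: float = DETECTION_BOX_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slide_width_um <= 0 or self.slide_height_um <= 0:
            raise ValueError("slide dimensions must be positive")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        if not 0.0 <= self.tumor_fraction < 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1)")
        for name in ("background_intensity", "cluster_parent_intensity", "cluster_mean_size", "cluster_sd_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def high_immunity_config(seed: int = 0) -> SimulationConfig:
    """Preset with many dense lymphocyte foci (focally clustered pattern)."""
    return SimulationConfig(
        background_intensity=100.0,
        cluster_parent_intensity=4.0,
        cluster_mean_size=45.0,
        cluster_sd_um=60.0,
        seed=seed,
    )


def low_immunity_config(seed: int = 0) -> SimulationConfig:
    """Preset with sparse-homogeneous infiltration and rare small foci."""
    return SimulationConfig(
        background_intensity=100.0,
        cluster_parent_intensity=1.0,
        cluster_mean_size=60.0,
        cluster_sd_um=15.0,
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort of labelled synthetic slides."""

    n_high: int = 20
    n_low: int = 20
    high_config: SimulationConfig = field(default_factory=high_immunity_config)
    low_config: SimulationConfig = field(default_factory=low_immunity_config)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_low < 0:
            raise ValueError("cohort sizes must be non-negative")


def _derive_seed(seed: int, index: int) -> int:
    """Deterministic per-slide seed from cohort seed and slide index."""
    return (seed * 100_003 + 7919 * index + index * index) % (2**31)


def _default_tissue(w: float, h: float) -> Polygon:
    margin = 0.05 * min(w, h)
    r = 0.08 * min(w, h)
    base = box(margin, margin, w - margin, h - margin)
    return base.buffer(-r).buffer(r, quad_segs=16)


def _sample_in_polygon(rng: np.random.Generator, poly, n: int, max_iter: int = 1000) -> np.ndarray:
    """Uniform points in a (multi)polygon via bounding-box rejection."""
    if n == 0:
        return np.zeros((0, 2))
    x0, y0, x1, y1 = poly.bounds
    pts: list[np.ndarray] = []
    need = n
    for _ in range(max_iter):
        m = max(64, int(need * max(1.5, (x1 - x0) * (y1 - y0) / max(poly.area, 1e-9))))
        cand = np.column_stack(
            [rng.uniform(x0, x1, size=m), rng.uniform(y0, y1, size=m)]
        )
        keep = shapely.intersects_xy(poly, cand[:, 0], cand[:, 1])
        got = cand[keep]
        if len(got):
            pts.append(got[:need])
            need -= len(got[:need])
        if need == 0:
            break
    if need > 0:
        raise RuntimeError("rejection sampling failed to fill the polygon")
    return np.concatenate(pts, axis=0)


def _simulate_tumors(rng: np.random.Generator, tissue: Polygon, fraction: float) -> list[Polygon]:
    """Random circular tumor blobs inside tissue totalling ~fraction of its area."""
    if fraction <= 0:
        return []
    target = fraction * tissue.area
    scale = math.sqrt(tissue.area)
    blobs: list[Polygon] = []
    covered = None
    for _ in range(200):
        center = _sample_in_polygon(rng, tissue, 1)[0]
        radius = rng.uniform(0.08, 0.16) * scale
        blob = shapely.Point(center).buffer(radius, quad_segs=12).intersection(tissue)
        geoms = [blob] if isinstance(blob, Polygon) else list(getattr(blob, "geoms", []))
        geoms = [g for g in geoms if isinstance(g, Polygon) and not g.is_empty]
        if not geoms:
            continue
        blobs.extend(geoms)
        covered = unary_union(blobs)
        if covered.area >= target:
            break
    return blobs


def simulate_slide(config: SimulationConfig, slide_id: str = "synthetic") -> SlideAnnotation:
    """Simulate one annotated slide; deterministic given ``config.seed``.

    Every emitted detection center lies inside the tissue polygon and
    outside all tumor polygons (stroma); cluster parents may fall anywhere
    in tissue but offspring outside stroma are rejected.
    """
    rng = np.random.default_rng(config.seed)
    tissue = config.tissue_shape or _default_tissue(config.slide_width_um, config.slide_height_um)
    tumors = _simulate_tumors(rng, tissue, config.tumor_fraction)
    stroma = tissue.difference(unary_union(tumors)) if tumors else tissue
    stroma_mm2 = stroma.area / UM2_PER_MM2
    tissue_mm2 = tissue.area / UM2_PER_MM2

    points: list[np.ndarray] = []
    n_bg = rng.poisson(config.background_intensity * stroma_mm2)
    if n_bg:
        points.append(_sample_in_polygon(rng, stroma, n_bg))

    n_parents = rng.poisson(config.cluster_parent_intensity * tissue_mm2)
    if n_parents and config.cluster_mean_size > 0:
        parents = _sample_in_polygon(rng, tissue, n_parents)
        for parent in parents:
            n_off = rng.poisson(config.cluster_mean_size)
            if n_off == 0:
                continue
            off = parent + rng.normal(0.0, config.cluster_sd_um, size=(n_off, 2))
            keep = shapely.intersects_xy(stroma, off[:, 0], off[:, 1])
            if keep.any():
                points.append(off[keep])

    centers_um = np.concatenate(points, axis=0) if points else np.zeros((0, 2))
    half = config.detection_box_um / 2.0
    mpp = config.mpp
    detections = [
        TILDetection(
            x_min=(x - half) / mpp,
            y_min=(y - half) / mpp,
            width=config.detection_box_um / mpp,
            height=config.detection_box_um / mpp,
        )
        for x, y in centers_um
    ]
    to_px = lambda poly: shapely.transform(poly, lambda a: a / mpp)
    return SlideAnnotation(
        slide_id=slide_id,
        mpp=mpp,
        tissue_polygons=[to_px(tissue)],
        tumor_polygons=[to_px(t) for t in tumors],
        detections=detections,
    )


def simulate_cohort(spec: SyntheticCohortSpec) -> list[tuple[SlideAnnotation, str]]:
    """Simulate a labelled cohort; bitwise reproducible for a fixed seed."""
    from .model import IMMUNITY_H, IMMUNITY_L

    out: list[tuple[SlideAnnotation, str]] = []
    for i in range(spec.n_high):
        cfg = replace(spec.high_config, seed=_derive_seed(spec.seed, i))
        out.append((simulate_slide(cfg, slide_id=f"synthetic-H{i:03d}"), IMMUNITY_H))
    for j in range(spec.n_low):
        cfg = replace(spec.low_config, seed=_derive_seed(spec.seed, spec.n_high + j))
        out.append((simulate_slide(cfg, slide_id=f"synthetic-L{j:03d}"), IMMUNITY_L))
    return out


# Group-level field-count magnitudes for the four markers (mean, SD per
# 400x field).  CD20 spreads are reported as median (IQR) in this setting;
# its scale is the normal-equivalent SD, IQR/1.349.
DEFAULT_IHC_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "high": {
        "CD3": (112.84, 28.76),
        "CD8": (22.98, 12.67),
        "CD20": (83.25, 33.26),
        "CD68": (61.28, 24.56),
    },
    "low": {
        "CD3": (44.98, 23.45),
        "CD8": (8.56, 7.89),
        "CD20": (37.00, 26.50),
        "CD68": (40.89, 22.13),
    },
}


@dataclass(frozen=True)
class IHCSimSpec:
    """Per-group, per-marker field-count distributions for the IHC simulator."""

    group_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_IHC_PARAMS
    )
    n_fields: int = 10
    family: Literal["truncnorm", "negbin"] = "truncnorm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 3:
            raise ValueError("n_fields must be at least 3 (trimming removes 2)")
        for group, markers in self.group_params.items():
            for marker, (mean, sd) in markers.items():
                if mean < 0 or sd < 0:
                    raise ValueError(f"negative mean/SD for {group}/{marker}")


def _draw_counts(rng: np.random.Generator, mean: float, sd: float, n: int, family: str) -> np.ndarray:
    if sd == 0:
        return np.full(n, round(mean), dtype=np.int64)
    if family == "truncnorm":
        vals = rng.normal(mean, sd, size=n)
        return np.maximum(0, np.rint(vals)).astype(np.int64)
    if family == "negbin":
        var = sd * sd
        if var <= mean:  # under-dispersed: fall back to Poisson
            return rng.poisson(mean, size=n).astype(np.int64)
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=n).astype(np.int64)
    raise ValueError(f"unknown count family {family!r}")


def simulate_ihc_cohort(spec: IHCSimSpec, n_cases_per_group: int) -> pd.DataFrame:
    """Simulate field counts: columns case_id, group, marker, field_index, count."""
    if n_cases_per_group < 0:
        raise ValueError("n_cases_per_group must be non-negative")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in spec.group_params:
        for i in range(n_cases_per_group):
            case_id = f"{group}-{i:03d}"
            for marker, (mean, sd) in spec.group_params[group].items():
                counts = _draw_counts(rng, mean, sd, spec.n_fields, spec.family)
                rows.extend(
                    {
                        "case_id": case_id,
                        "group": group,
                        "marker": marker,
                        "field_index": k,
                        "count": int(c),
                    }
                    for k, c in enumerate(counts)
                )
    return pd.DataFrame(rows, columns=["case_id", "group", "marker", "field_index", "count"])


def render_synthetic_image(
    annotation: SlideAnnotation,
    mpp_out: float = 4.0,
    *,
    noise_sd: float = 4.0,
    margin_um: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize an annotation into an RGB image plus ground-truth mask.

    Background is near-white, tissue interior tinted pink with Gaussian
    texture noise (a crude stand-in for stained tissue on a bright scanner
    field).  Returns ``(image, mask)`` with image uint8 (H, W, 3) at
    ``mpp_out`` microns per pixel and mask the boolean tissue rasterization.
    """
    from skimage.draw import polygon as draw_polygon

    if not annotation.tissue_polygons:
        raise ValueError("annotation has no tissue polygons")
    mpp_in = annotation.mpp
    union = unary_union(annotation.tissue_polygons)
    x0, y0, x1, y1 = (v * mpp_in for v in union.bounds)
    x0 -= margin_um
    y0 -= margin_um
    w = int(math.ceil((x1 - x0 + margin_um) / mpp_out))
    h = int(math.ceil((y1 - y0 + margin_um) / mpp_out))

    mask = np.zeros((h, w), dtype=bool)
    for poly in annotation.tissue_polygons:
        ext = np.asarray(poly.exterior.coords)
        rr, cc = draw_polygon(
            (ext[:, 1] * mpp_in - y0) / mpp_out, (ext[:, 0] * mpp_in - x0) / mpp_out, shape=mask.shape
        )
        mask[rr, cc] = True
        for ring in poly.interiors:
            interior = np.asarray(ring.coords)
            rr, cc = draw_polygon(
                (interior[:, 1] * mpp_in - y0) / mpp_out,
                (interior[:, 0] * mpp_in - x0) / mpp_out,
                shape=mask.shape,
            )
            mask[rr, cc] = False

    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = (246.0, 246.0, 246.0)
    tint = np.array([214.0, 176.0, 208.0])
    img[mask] = tint
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask
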