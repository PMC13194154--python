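"""Reading and writing slide annotations.

Annotations follow the QuPath convention: geometries are stored in level-0
pixel coordinates of the source slide, with a separate microns-per-pixel
(``mpp``) scale factor; every computation in micron space converts via
``um = px * mpp`` at the point of use.  Features are classed by
``properties.classification.name``: ``"Tissue"`` for tissue contours,
``"Tumor"`` for tumor parenchyma and ``"TIL"`` for lymphocyte detections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from shapely.geometry import Point, Polygon, mapping, shape
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

TISSUE_CLASS = "Tissue"
TUMOR_CLASS = "Tumor"
TIL_CLASS = "TIL"


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid geometry."""


@dataclass(frozen=True)
class TILDetection:
    """One lymphocyte detection as an axis-aligned bounding box (level-0 px).

    Downstream rules consume only the box *center*; the extent is carried so
    round trips preserve the original annotation.
    """

    x_min: float
    y_min: float
    width: float
    height: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise AnnotationError("detection box must have non-negative extent")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise AnnotationError("confidence must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min + self.width / 2.0, self.y_min + self.height / 2.0)


@dataclass
class SlideAnnotation:
    """All annotations for one slide: tissue contours, tumor parenchyma, TILs."""

    slide_id: str
    mpp: float
    tissue_polygons: list[Polygon] = field(default_factory=list)
    tumor_polygons: list[Polygon] = field(default_factory=list)
    detections: list[TILDetection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mpp > 0:
            raise AnnotationError(f"mpp must be positive, got {self.mpp}")
        self.tissue_polygons = [_validate_polygon(p) for p in self.tissue_polygons]
        self.tumor_polygons = [_validate_polygon(p) for p in self.tumor_polygons]

    def detection_centers_um(self) -> list[tuple[float, float]]:
        """Box centers converted to micron space."""
        return [(cx * self.mpp, cy * self.mpp) for cx, cy in (d.center for d in self.detections)]


def _validate_polygon(poly: Polygon) -> Polygon:
    """Validate a polygon; attempt zero-buffer repair, reject if still invalid.

    Holes are allowed (interior rings subtract area).
    """
    if not isinstance(poly, Polygon):
        raise AnnotationError(f"expected Polygon geometry, got {type(poly).__name__}")
    if len(poly.exterior.coords) < 4:  # closed ring: 3 vertices -> 4 coords
        raise AnnotationError("polygon must have at least 3 vertices")
    if poly.is_valid:
        return poly
    repaired = poly.buffer(0)
    if isinstance(repaired, Polygon) and repaired.is_valid and not repaired.is_empty:
        logger.warning("repaired self-intersecting polygon via zero-buffer")
        return repaired
    repaired = make_valid(poly)
    if isinstance(repaired, Polygon) and repaired.is_valid and not repaired.is_empty:
        logger.warning("repaired invalid polygon via make_valid")
        return repaired
    raise AnnotationError("self-intersecting polygon could not be repaired")


def _detection_to_feature(det: TILDetection) -> dict:
    if det.width == 0 and det.height == 0:
        geom = mapping(Point(det.x_min, det.y_min))
    else:
        x0, y0 = det.x_min, det.y_min
        x1, y1 = x0 + det.width, y0 + det.height
        geom = mapping(Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]))
    props: dict = {"classification": {"name": TIL_CLASS}}
    if det.confidence is not None:
        props["confidence"] = det.confidence
    return {"type": "Feature", "geometry": geom, "properties": props}


def write_annotations(annotation: SlideAnnotation, path: str | Path) -> None:
    """Write a :class:`SlideAnnotation` as a GeoJSON FeatureCollection.

    The slide id and mpp scale live in a top-level ``metadata`` block;
    features carry QuPath-style ``properties.classification.name``.
    """
    features: list[dict] = []
    for cls, polys in ((TISSUE_CLASS, annotation.tissue_polygons), (TUMOR_CLASS, annotation.tumor_polygons)):
        for poly in polys:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {"classification": {"name": cls}},
                }
            )
    features.extend(_detection_to_feature(d) for d in annotation.detections)
    doc = {
        "type": "FeatureCollection",
        "metadata": {"slide_id": annotation.slide_id, "mpp": annotation.mpp},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_annotations(
    path: str | Path,
    *,
    mpp: float | None = None,
    slide_id: str | None = None,
    point_box_size: float = 0.0,
) -> SlideAnnotation:
    """Read a GeoJSON/JSON annotation file into a :class:`SlideAnnotation`.

    Parameters
    ----------
    path
        GeoJSON FeatureCollection (or the plain-JSON mirror of it).
    mpp
        Override for the microns-per-pixel scale when the file has none.
    slide_id
        Override for the slide identifier (defaults to metadata, then stem).
    point_box_size
        Side length (px) of the box substituted for Point TIL features;
        the default 0 keeps them as zero-area boxes centred on the point.

    TIL features given as polygons are reduced to their bounding box, whose
    center equals the rectangle centroid for axis-aligned rectangles.
    Features with unknown classification names are counted and reported via
    the logger, never silently dropped from the accounting.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path} is not valid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise AnnotationError(f"{path} is not a FeatureCollection")

    meta = doc.get("metadata", {})
    file_mpp = meta.get("mpp")
    eff_mpp = mpp if mpp is not None else file_mpp
    if eff_mpp is None:
        raise AnnotationError(f"{path} has no mpp metadata and no override was supplied")
    sid = slide_id or meta.get("slide_id") or path.stem

    tissue: list[Polygon] = []
    tumor: list[Polygon] = []
    detections: list[TILDetection] = []
    unknown: dict[str, int] = {}

    for feat in doc["features"]:
        props = feat.get("properties") or {}
        cls = (props.get("classification") or {}).get("name", "")
        geom = shape(feat["geometry"])
        if cls == TISSUE_CLASS:
            tissue.append(_validate_polygon(geom))
        elif cls == TUMOR_CLASS:
            tumor.append(_validate_polygon(geom))
        elif cls == TIL_CLASS:
            detections.append(_geom_to_detection(geom, props.get("confidence"), point_box_size))
        else:
            unknown[cls or "<unclassified>"] = unknown.get(cls or "<unclassified>", 0) + 1

    if unknown:
        logger.warning("%s: skipped features with unknown classes: %s", path, unknown)
    n_total = len(doc["features"])
    n_used = len(tissue) + len(tumor) + len(detections)
    assert n_used + sum(unknown.values()) == n_total
    logger.info("%s: %d tissue, %d tumor, %d TIL features", path, len(tissue), len(tumor), len(detections))

    return SlideAnnotation(
        slide_id=sid, mpp=float(eff_mpp), tissue_polygons=tissue, tumor_polygons=tumor, detections=detections
    )


def _geom_to_detection(geom, confidence, point_box_size: float) -> TILDetection:
    if isinstance(geom, Point):
        s = float(point_box_size)
        return TILDetection(geom.x - s / 2.0, geom.y - s / 2.0, s, s, confidence)
    x0, y0, x1, y1 = geom.bounds
    return TILDetection(x0, y0, x1 - x0, y1 - y0, confidence)


def point_in_tissue(x: float, y: float, polygons: Iterable[Polygon]) -> bool:
    """Even-odd point-in-polygon test; boundary points count as inside."""
    pt = Point(x, y)
    return any(poly.covers(pt) for poly in polygons)
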