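import numpy as np
import pytest
from shapely.geometry import box

from tilscore import GridConfig, SlideAnnotation, TILDetection


def make_detection(x_um: float, y_um: float, mpp: float = 1.0, size_um: float = 8.0) -> TILDetection:
    """Detection whose box center sits at (x_um, y_um)."""
    return TILDetection(
        x_min=(x_um - size_um / 2) / mpp,
        y_min=(y_um - size_um / 2) / mpp,
        width=size_um / mpp,
        height=size_um / mpp,
    )


def rect_annotation(
    width_um: float,
    height_um: float,
    detections_um=(),
    tumor_boxes_um=(),
    mpp: float = 1.0,
    slide_id: str = "fixture",
) -> SlideAnnotation:
    """Rectangular tissue slab with optional tumor boxes and detections (μm)."""
    return SlideAnnotation(
        slide_id=slide_id,
        mpp=mpp,
        tissue_polygons=[box(0, 0, width_um / mpp, height_um / mpp)],
        tumor_polygons=[
            box(x0 / mpp, y0 / mpp, x1 / mpp, y1 / mpp) for x0, y0, x1, y1 in tumor_boxes_um
        ],
        detections=[make_detection(x, y, mpp=mpp) for x, y in detections_um],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def grid_config():
    return GridConfig(patch_size_um=100.0)
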