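import numpy as np
import pytest
from shapely.geometry import Point, box

from tilscore import GridConfig, build_patch_grid, count_tils, normalize_density, quantify_slide

from conftest import make_detection, rect_annotation


@pytest.mark.parametrize(
    "w,h,expected",
    [
        (1000, 1000, (10, 10)),
        (250, 250, (3, 3)),
        (999, 1, (1, 10)),  # ceil(999/100)=10 columns, one 1-um row
        (100, 100, (1, 1)),
    ],
)
def test_grid_dimensions_cover_bounding_box(w, h, expected):
    grid = build_patch_grid(rect_annotation(w, h), GridConfig(patch_size_um=100))
    assert (grid.n_rows, grid.n_cols) == expected
    assert len(grid.patches) == expected[0] * expected[1]


def test_grid_respects_mpp_scaling():
    # same physical extent expressed at a different pixel scale
    grid = build_patch_grid(rect_annotation(1000, 1000, mpp=0.25), GridConfig(patch_size_um=100))
    assert (grid.n_rows, grid.n_cols) == (10, 10)


def test_requires_tissue_polygons():
    ann = rect_annotation(100, 100)
    ann.tissue_polygons = []
    with pytest.raises(ValueError, match="tissue"):
        build_patch_grid(ann)


def test_counts_and_num_max_on_known_layout(grid_config):
    # 4 in patch (0,0), 2 in (1,1), 1 in (3,2)
    pts = [(10, 10), (20, 20), (30, 30), (40, 40), (150, 150), (160, 160), (250, 350)]
    ann = rect_annotation(400, 400, detections_um=pts)
    grid = count_tils(build_patch_grid(ann, grid_config), ann)
    counts = grid.counts_array()
    assert counts.sum() == 7
    assert grid.num_max == 4
    assert counts[0, 0] == 4 and counts[1, 1] == 2 and counts[3, 2] == 1
    assert sum(p.is_valid for p in grid.patches) == 3


def test_detection_in_tumor_is_not_counted(grid_config):
    ann = rect_annotation(
        200, 200, detections_um=[(50, 50), (150, 150)], tumor_boxes_um=[(100, 100, 200, 200)]
    )
    grid = count_tils(build_patch_grid(ann, grid_config), ann)
    assert grid.counts_array().sum() == 1  # (150,150) center is inside tumor


def test_detection_on_tumor_boundary_counts_as_inside_tumor(grid_config):
    ann = rect_annotation(200, 200, detections_um=[(100, 50)], tumor_boxes_um=[(100, 0, 200, 100)])
    grid = count_tils(build_patch_grid(ann, grid_config), ann)
    assert grid.counts_array().sum() == 0


def test_half_open_boundary_goes_to_right_hand_patch(grid_config):
    # center exactly on the shared boundary x=100 between cols 0 and 1
    ann = rect_annotation(200, 200, detections_um=[(100, 50)])
    grid = count_tils(build_patch_grid(ann, grid_config), ann)
    counts = grid.counts_array()
    assert counts[0, 1] == 1 and counts[0, 0] == 0


def test_far_edge_detection_is_clamped_into_last_patch(grid_config):
    ann = rect_annotation(200, 200, detections_um=[(200, 200)])
    grid = count_tils(build_patch_grid(ann, grid_config), ann)
    assert grid.counts_array()[1, 1] == 1


def test_normalization_formula(grid_config):
    ann = rect_annotation(
        300, 100,
        detections_um=[(50, 50)] * 2 + [(150, 50)] * 8 + [(250, 50)] * 4,
    )
    grid = normalize_density(count_tils(build_patch_grid(ann, grid_config), ann))
    assert grid.num_max == 8
    assert [p.a for p in grid.patches] == pytest.approx([0.25, 1.0, 0.5])
    assert not grid.degenerate


def test_degenerate_slide_flags_and_zero_densities(grid_config):
    ann = rect_annotation(300, 100)
    grid = normalize_density(count_tils(build_patch_grid(ann, grid_config), ann))
    assert grid.degenerate
    assert all(p.a == 0.0 for p in grid.patches)
    assert not any(p.is_valid for p in grid.patches)


def test_single_nonzero_patch_self_normalizes(grid_config):
    ann = rect_annotation(300, 100, detections_um=[(150, 50)] * 5)
    grid = normalize_density(count_tils(build_patch_grid(ann, grid_config), ann))
    assert max(p.a for p in grid.patches) == 1.0


def brute_force_counts(ann, grid):
    """Independent recount: per-detection polygon tests + rectangle scan."""
    s = grid.config.patch_size_um
    x0, y0 = grid.origin_um
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    for det in ann.detections:
        cx, cy = det.center
        cx_um, cy_um = cx * ann.mpp, cy * ann.mpp
        pt = Point(cx, cy)
        if not any(t.covers(pt) for t in ann.tissue_polygons):
            continue
        if any(t.covers(pt) for t in ann.tumor_polygons):
            continue
        placed = False
        for p in grid.patches:
            if p.x0_um <= cx_um < p.x0_um + s and p.y0_um <= cy_um < p.y0_um + s:
                counts[p.row, p.col] += 1
                placed = True
                break
        if not placed:  # far-edge clamp convention
            r = min(int((cy_um - y0) // s), grid.n_rows - 1)
            c = min(int((cx_um - x0) // s), grid.n_cols - 1)
            counts[r, c] += 1
    return counts


def test_count_conservation_against_brute_force_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(0, 500))
        w, h = rng.uniform(200, 800, size=2)
        tumors = []
        if rng.random() < 0.7:
            tx, ty = rng.uniform(0, w / 2), rng.uniform(0, h / 2)
            tumors.append((tx, ty, tx + rng.uniform(50, w / 2), ty + rng.uniform(50, h / 2)))
        pts = [tuple(p) for p in np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])]
        ann = rect_annotation(w, h, detections_um=pts, tumor_boxes_um=tumors)
        grid = count_tils(build_patch_grid(ann), ann)
        expected = brute_force_counts(ann, grid)
        np.testing.assert_array_equal(grid.counts_array(), expected)
        assert grid.num_max == expected.max()


def test_translation_by_patch_multiples_permutes_counts(rng):
    n = 200
    pts = np.column_stack([rng.uniform(0, 500, n), rng.uniform(0, 400, n)])
    ann = rect_annotation(500, 400, detections_um=[tuple(p) for p in pts])
    grid = count_tils(build_patch_grid(ann), ann)
    shifted = rect_annotation(500, 400, detections_um=[(x, y) for x, y in pts])
    dx, dy = 300.0, 200.0  # integer multiples of the 100-um patch size
    from shapely.affinity import translate

    shifted.tissue_polygons = [translate(p, xoff=dx, yoff=dy) for p in shifted.tissue_polygons]
    shifted.detections = [make_detection(x + dx, y + dy) for x, y in pts]
    grid2 = count_tils(build_patch_grid(shifted), shifted)
    assert sorted(grid.counts_array().ravel()) == sorted(grid2.counts_array().ravel())


def test_density_scale_invariance(grid_config):
    pts = [(50, 50)] * 3 + [(150, 50)] * 6
    ann1 = rect_annotation(200, 100, detections_um=pts)
    ann2 = rect_annotation(200, 100, detections_um=pts * 4)  # all counts x4
    g1 = quantify_slide(ann1, grid_config)
    g2 = quantify_slide(ann2, grid_config)
    assert [p.a for p in g1.patches] == pytest.approx([p.a for p in g2.patches])


def test_min_tissue_fraction_qc_invalidates_edge_patches():
    # tissue is a 150x100 um slab: column 1 patches have 50% tissue coverage
    ann = rect_annotation(150, 100, detections_um=[(50, 50), (125, 50)])
    grid = count_tils(build_patch_grid(ann, GridConfig(min_tissue_fraction=0.6)), ann)
    by_col = {p.col: p for p in grid.patches}
    assert by_col[0].is_valid
    assert not by_col[1].is_valid  # has a TIL but fails the 60% tissue QC
    assert by_col[1].tissue_fraction == pytest.approx(0.5)


def test_slide_id_mismatch_raises(grid_config):
    a = rect_annotation(100, 100, slide_id="a")
    b = rect_annotation(100, 100, slide_id="b")
    grid = build_patch_grid(a, grid_config)
    with pytest.raises(ValueError, match="grid built for"):
        count_tils(grid, b)
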