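import numpy as np
import pytest

from tilscore import (
    GridConfig,
    ModelConfig,
    TILSubtypeModel,
    calibrate_attention_threshold,
    calibrate_score_threshold,
    classify_slide,
    compute_slide_score,
    flag_high_attention,
    quantify_slide,
    score_slide,
)
from tilscore.grid import PatchRecord, SlideGrid
from tilscore.model import IMMUNITY_H, IMMUNITY_L

from conftest import rect_annotation


def grid_from_counts(counts):
    """Synthetic SlideGrid straight from a count matrix (no geometry)."""
    counts = np.asarray(counts, dtype=int)
    n_rows, n_cols = counts.shape
    num_max = int(counts.max())
    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            n = int(counts[r, c])
            patches.append(
                PatchRecord(
                    row=r, col=c, x0_um=c * 100.0, y0_um=r * 100.0,
                    num_tils=n, a=(n / num_max if num_max else 0.0), is_valid=n >= 1,
                )
            )
    return SlideGrid(
        slide_id="synthetic-counts", config=GridConfig(), n_rows=n_rows, n_cols=n_cols,
        origin_um=(0.0, 0.0), patches=patches, num_max=num_max, degenerate=num_max == 0,
    )


def test_attention_flag_is_strict():
    grid = grid_from_counts([[10, 20, 21, 100]])
    flag_high_attention(grid, 0.2)  # a = 0.1, 0.2, 0.21, 1.0
    assert [p.is_high_attention for p in grid.patches] == [False, False, True, True]


def test_no_flags_when_all_densities_zero():
    grid = grid_from_counts([[0, 0, 0]])
    flag_high_attention(grid, 0.2)
    assert not any(p.is_high_attention for p in grid.patches)


def test_bimodal_fixture_flags_exactly_high_cluster(rng):
    low = rng.uniform(0.0, 0.1, size=40)
    high = rng.uniform(0.4, 0.6, size=9)
    a_vals = np.concatenate([low, high, [1.0]])
    grid = grid_from_counts(np.ones((1, len(a_vals)), dtype=int))
    for p, a in zip(grid.patches, a_vals):
        p.a = float(a)
    flag_high_attention(grid, 0.2)
    assert sum(p.is_high_attention for p in grid.patches) == 10


def test_score_formula():
    counts = np.zeros((10, 10), dtype=int)
    counts[0, :4] = 30  # 4 high-attention patches
    counts.flat[40:136:1] = 1  # fill most remaining with singletons
    grid = grid_from_counts(counts)
    flag_high_attention(grid, 0.2)
    ss = compute_slide_score(grid)
    assert ss.n_high == 4
    assert ss.score == pytest.approx(ss.n_high / ss.n_valid)


def test_engineered_ratio_just_above_threshold():
    # n_high=5, n_valid=85 -> score 1/17 ~ 0.0588 > 0.05 -> Immunity_H
    counts = np.zeros((1, 85), dtype=int)
    counts[0, :5] = 20
    counts[0, 5:] = 1
    grid = grid_from_counts(counts)
    flag_high_attention(grid, 0.2)
    ss = compute_slide_score(grid)
    assert (ss.n_high, ss.n_valid) == (5, 85)
    assert ss.score == pytest.approx(1 / 17)
    assert ss.label == IMMUNITY_H


def test_zero_high_patches_scores_zero():
    grid = grid_from_counts([[1, 1, 2]])
    for p in grid.patches:
        p.a = 0.1  # every valid patch below the attention cutoff
    flag_high_attention(grid, 0.2)
    ss = compute_slide_score(grid)
    assert ss.n_high == 0 and ss.score == 0.0


@pytest.mark.parametrize(
    "score,label",
    [
        (0.058781, IMMUNITY_H),
        (0.042932, IMMUNITY_L),
        (0.05, IMMUNITY_L),  # strict inequality at the boundary
        (0.050001, IMMUNITY_H),
        (0.0, IMMUNITY_L),
    ],
)
def test_classification_rule(score, label):
    assert classify_slide(score, 0.05) == label


def test_degenerate_slide_is_low_immunity(grid_config):
    ann = rect_annotation(300, 300)
    ss = score_slide(ann)
    assert ss.degenerate and ss.score == 0.0 and ss.label == IMMUNITY_L


def test_attention_calibration_lands_in_constructed_gap(rng):
    vals = np.concatenate([rng.uniform(0.0, 0.1, 200), rng.uniform(0.4, 0.6, 40)])
    thr, diag = calibrate_attention_threshold(vals)
    assert 0.1 < thr < 0.4
    assert not diag["unimodal"]
    assert diag["n_lower"] == 200 and diag["n_upper"] == 40


def test_attention_calibration_midpoint_of_two_levels():
    vals = [0.1] * 5 + [0.9] * 5
    thr, _ = calibrate_attention_threshold(vals)
    assert thr == pytest.approx(0.5)


def test_attention_calibration_falls_back_on_unimodal_input(rng):
    vals = rng.uniform(0.0, 1.0, 500)
    with pytest.warns(UserWarning, match="unimodal"):
        thr, diag = calibrate_attention_threshold(vals)
    assert thr == 0.2
    assert diag["unimodal"]


def test_attention_calibration_needs_ten_values():
    with pytest.raises(ValueError, match="10"):
        calibrate_attention_threshold([0.1, 0.9])


def test_score_calibration_separates_perfectly():
    scores = [0.01, 0.02, 0.03, 0.2, 0.3, 0.4]
    labels = [IMMUNITY_L] * 3 + [IMMUNITY_H] * 3
    thr, sweep = calibrate_score_threshold(scores, labels)
    assert 0.03 <= thr < 0.2
    assert sweep["accuracy"].max() == 1.0
    pred = [classify_slide(s, thr) for s in scores]
    assert pred == labels


def test_score_calibration_on_example_test_set():
    from tilscore.datasets import example_score_table

    df = example_score_table()
    thr, sweep = calibrate_score_threshold(df["score"], df["reference"])
    best_acc = sweep["accuracy"].max()
    assert best_acc >= 0.9


def test_score_calibration_rejects_single_class():
    with pytest.raises(ValueError):
        calibrate_score_threshold([0.1, 0.2, 0.3], [IMMUNITY_L] * 3)


def test_permuted_labels_give_near_chance_accuracy(rng):
    scores = rng.uniform(0, 1, 40)
    accs = []
    for _ in range(50):
        labels = np.where(rng.permutation(40) < 20, IMMUNITY_H, IMMUNITY_L)
        _, sweep = calibrate_score_threshold(scores, labels)
        accs.append(sweep["accuracy"].max())
    # optimized accuracy on random labels: chance (0.5) plus optimism, well below perfect
    assert 0.5 < np.mean(accs) < 0.75


def test_score_monotone_in_attention_threshold(rng):
    for _ in range(20):
        counts = rng.integers(0, 30, size=(8, 8))
        grid = grid_from_counts(counts)
        prev = None
        for thr in (0.05, 0.2, 0.4, 0.6, 0.9):
            flag_high_attention(grid, thr)
            s = compute_slide_score(grid).score
            if prev is not None:
                assert s <= prev + 1e-12
            prev = s


def test_adding_high_patch_never_decreases_score(rng):
    counts = rng.integers(0, 10, size=(5, 5))
    counts[0, 0] = 20
    grid = grid_from_counts(counts)
    flag_high_attention(grid, 0.2)
    base = compute_slide_score(grid)
    bigger = counts.copy()
    bigger[4, 4] = 20  # extra high-attention patch
    grid2 = grid_from_counts(bigger)
    flag_high_attention(grid2, 0.2)
    assert compute_slide_score(grid2).score >= base.score


def brute_force_score(ann, attention_threshold=0.2):
    """Independent Score recomputation straight from raw detections."""
    from shapely.geometry import Point

    s = 100.0
    xs0, ys0, xs1, ys1 = ann.tissue_polygons[0].bounds
    x0, y0 = xs0 * ann.mpp, ys0 * ann.mpp
    counts: dict[tuple[int, int], int] = {}
    for det in ann.detections:
        cx, cy = det.center
        pt = Point(cx, cy)
        if not any(t.covers(pt) for t in ann.tissue_polygons):
            continue
        if any(t.covers(pt) for t in ann.tumor_polygons):
            continue
        key = (int((cy * ann.mpp - y0) // s), int((cx * ann.mpp - x0) // s))
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        return 0.0
    num_max = max(counts.values())
    n_valid = len(counts)
    n_high = sum(1 for v in counts.values() if v / num_max > attention_threshold)
    return n_high / n_valid


def test_score_matches_brute_force_from_raw_detections(rng):
    for _ in range(10):
        n = int(rng.integers(20, 200))
        pts = [tuple(p) for p in np.column_stack([rng.uniform(0, 900, n), rng.uniform(0, 700, n)])]
        ann = rect_annotation(900, 700, detections_um=pts, tumor_boxes_um=[(0, 0, 300, 200)])
        ss = score_slide(ann)
        assert ss.score == pytest.approx(brute_force_score(ann))


def test_model_fit_and_summary(rng):
    anns, labels = [], []
    for i in range(3):
        n = 120
        pts = [tuple(p) for p in np.column_stack([rng.uniform(0, 500, n), rng.uniform(0, 500, n)])]
        ann = rect_annotation(500, 500, detections_um=pts, slide_id=f"s{i}")
        anns.append(ann)
        labels.append(IMMUNITY_L)
    model = TILSubtypeModel(anns, labels=labels)
    res = model.fit()
    assert list(res.scores["slide_id"]) == ["s0", "s1", "s2"]
    text = res.summary()
    assert "a > 0.2" in text and "Score > 0.05" in text
    cm, report = res.evaluate()
    assert cm.total == 3


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(attention_threshold=0.0)
    with pytest.raises(ValueError):
        ModelConfig(score_threshold=1.0)
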