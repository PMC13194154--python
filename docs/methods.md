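# Methods

## The scoring model

A slide enters the pipeline as a set of tissue-contour polygons,
tumor-parenchyma polygons, and TIL detections (axis-aligned boxes), all in
level-0 pixel coordinates with a microns-per-pixel scale `mpp` (QuPath
convention). Every micron-space quantity is derived as `μm = px × mpp` at
the point of use.

**Patch grid.** The joint bounding box of the tissue polygons is tiled
with non-overlapping square patches, side 100 μm by default. The "sliding
window with 100 μm step" is realized as a partition (window = step):
the score's denominator counts patches, which presumes non-overlap, and
overlapping windows would double-count detections. The grid is anchored at
the bounding-box minimum corner, making it deterministic. Patches are
half-open squares `[x0, x0+s) × [y0, y0+s)` so a detection center on a
shared boundary belongs to exactly one patch (the right/lower neighbour);
a center exactly on the far edge of the grid — a measure-zero event — is
clamped into the last patch. Partial patches at the far edges are kept.

**Stromal filter.** A detection is counted iff its box center lies inside
a tissue polygon and outside every tumor polygon. Point-in-polygon uses
the even-odd rule with boundary points counting as inside — for tumor
polygons too, so a center on a tumor boundary is treated as tumor, not
stroma. The filter is applied to detections, not patch geometry: a patch
straddling a tumor boundary still collects its stromal detections.

**Normalization and validity.** Per-patch counts are normalized by the
slide maximum, `a = Num / NumMax`, so `a ∈ [0, 1]` and at least one patch
has `a = 1` whenever anything was counted. A patch is *valid* when it
contains at least one counted TIL; an optional QC switch additionally
requires ≥ 60% tissue coverage per patch (off by default — that filter
belongs to training-data curation, not scoring). A slide with no counted
TILs at all is *degenerate*: all `a` are set to 0, the Score is defined as
0, the label is `Immunity_L`, and a loud warning is logged, since a
no-TIL slide is trivially "cold" but worth a human look.

**Decision rule.** High-attention patches are the valid patches with
`a > 0.2` (strict); `Score = N_high / N_valid`; `Immunity_H` iff
`Score > 0.05` (strict). Strictness matters only on exact boundary values
and is pinned by tests.

**Threshold calibration.** The attention threshold can be re-derived from
the pooled valid-patch densities: Ward-linkage agglomerative clustering of
the 1-D values cut at k = 2, threshold at the midpoint between the lower
cluster's maximum and the upper cluster's minimum. Ward was chosen among
hierarchical linkages because it is variance-based and robust for 1-D mode
separation; for a genuinely bimodal sample any k=2 cut that lands in the
gap is equivalent. If the inter-cluster gap is below 0.02 the sample is
treated as unimodal and the default 0.2 is returned with a warning —
clustering always "finds" two clusters, so the gap test guards against
meaningless cuts. Inputs beyond 50,000 values are subsampled with a fixed
seed. The score threshold is calibrated against reference labels by
sweeping candidate cutoffs at midpoints between consecutive sorted unique
scores and maximizing accuracy; ties break by Youden's J, then by the
smallest threshold (preferring sensitivity). Accuracy was chosen as the
objective because the rule is meant as a balanced binary triage; the full
sweep table is returned so a user can pick a different operating point.

## Synthetic slides

The generator emulates what an upstream annotation pipeline (tissue
segmentation + lymphocyte detection) would emit, not what tissue looks
like. Geometry: a rounded-rectangle tissue polygon inset 5% from the slide
bounds; tumor parenchyma as random discs clipped to tissue until they
cover ~30% of tissue area. TILs are placed in stroma by superposing a
homogeneous Poisson process (rate per mm² of stroma) and a Thomas cluster
process (Poisson parents per mm² of tissue; Poisson offspring counts;
isotropic Gaussian displacement; offspring outside stroma rejected).
Detections are 8 μm boxes — a lymphocyte-nucleus diameter — centered on
the points, since downstream rules consume box centers only.

The two cohort presets are calibrated to produce the qualitative structure
the rule assumes, on 3 × 3 mm slides (≈ 7.3 mm² tissue, ≈ 900 patches):

* **high-immunity**: background 100 cells/mm², parents 4.0/mm², mean 45
  offspring, σ = 60 μm — many multi-patch aggregation foci; Scores land
  around 0.1–0.3.
* **low-immunity**: background 100 cells/mm², parents 1.0/mm², mean 60
  offspring, σ = 15 μm — sparse diffuse infiltration with a few tight
  foci; Scores land around 0.01–0.05.

The low preset deliberately includes rare dense foci: with `a = Num/NumMax`
normalization, a slide whose maximum patch count is small (≤ 5) has
`1/NumMax ≥ 0.2`, so *every* TIL-containing patch would clear the
attention cutoff and the Score saturates. Real "cold" slides still contain
occasional lymphoid aggregates; the preset encodes that, and it is also
what makes the normalization well-behaved. No quantitative densities were
available for the source cohorts, so these magnitudes are an order-of-
magnitude choice for visibly hot vs. cold H&E slides; the separation
experiment (20+20 slides, label recovery ≥ 90%) is therefore a check of
pipeline correctness under the generator's assumptions, not a claim about
clinical accuracy on real WSIs. The generator does not emulate detector
false positives/negatives, staining variation, or nucleus morphology.

Per-slide seeds derive from the cohort seed as
`(seed·100003 + 7919·i + i²) mod 2³¹`; no global RNG state is touched.

The IHC simulator draws 10 field counts per case/marker from truncated
rounded normals (negative binomial available) with group means/SDs set to
the magnitudes observed in immunostained LUAD cohorts (e.g. CD3: 112.84 ±
28.76 high vs. 44.98 ± 23.45 low). CD20 spreads are published as median
(IQR) in this setting; the simulator uses the median as location and
IQR/1.349 (the normal-equivalent SD) as scale.

## Tissue mask

The classical pipeline: rescale to the pixel pitch of a 2.5× objective
(4 μm/px, computed from the input `mpp`; fixed 1/16 fallback without one) →
grayscale → Roberts gradient binarized by Otsu → union with Canny edges at
thresholds (30, 120) on the 0–255 scale → two binary closings with a 3×3
elliptical element → border flood-fill of internal holes → removal of
components below 0.1% of frame area. Roberts/Otsu and Canny are combined
by union because the union maximizes weak-boundary recall; the stage
composition here is one faithful reading of a pipeline whose exact
ordering is underdetermined, fixed by the round-trip requirement (Dice ≥
0.95 against the synthetic ground truth). Preprocessing runs the 3×3
median *before* the σ = 1.5 Gaussian so impulse noise is removed rather
than smeared; missing pixels are filled by bilinear interpolation from
valid neighbours (nearest-neighbour outside their convex hull).
Mask-overlap metrics define empty-vs-empty as 1.0 and a metric whose
denominator alone is empty as 0.0.

## Heatmaps

Per-patch densities are interpolated bilinearly between patch-center nodes
onto a fine grid (default 8 × 8 cells per patch). Coordinates are clamped
to the node hull, i.e. constant extension in the outer half-patch band, so
by convexity the surface never leaves the input range and passes exactly
through the node values. Fine cells outside tissue are masked by default
(transparent), with a flag to interpolate across them instead. The
colormap is fixed — blue at a = 0 through red at a = 1 — so color is
comparable across slides; rendering is deterministic to the byte.

## Evaluation statistics

Positive class is high immunity throughout. Accuracy, sensitivity,
specificity, PPV and NPV come with Wilson score 95% intervals
(z = 1.959964); Wilson was adopted because it is the standard
recommendation for small-n proportions, reproduces the published reference
intervals for accuracy/sensitivity/specificity/NPV exactly at one-decimal
rounding, and behaves at the 0/n and n/n boundaries. The published PPV
interval (76.5–98.1% for 26/28) is *not* Wilson (≈ 77.4–98.0%); the
package standardizes on Wilson and documents the discrepancy rather than
guessing the original method. Metrics with zero denominators are reported
as absent, never NaN. AUC is the trapezoidal area under the empirical ROC,
which equals the Mann–Whitney probability with ties counting ½; a
brute-force pair-counting oracle pins this in the tests. No AUC confidence
intervals are provided (the original interval method is unstated and would
need the real cohorts).

IHC reference standard: per marker, drop exactly one maximal and one
minimal field count, average the rest, divide by the 0.2595 mm² HPF area,
Z-score across the cohort (sample SD, n−1), average the four marker
Z-scores, and dichotomize at the cohort median (strict `>` → high; a
composite equal to the median is low). A marker with zero cohort SD gets
Z = 0 with a warning instead of failing the panel.

## Problem sizes and determinism

Tests and the acceptance script run on 3 × 3 mm synthetic slides (≈ 900
patches, 10³–10⁴ detections), 20+20-slide cohorts, 30+30-case IHC cohorts,
and 500-replicate Poisson-mean checks — sizes at which the Monte-Carlo
tolerances stated in each test (e.g. 3 standard errors) are meaningful and
the whole suite stays fast. Everything stochastic is seeded; cohort
simulation is bitwise reproducible for a fixed seed.

## Known limitations

* Detections arrive pre-computed; the package performs no nucleus
  detection and does not model detector error.
* The example test set's one discordant case is recorded with its
  transcriptomic reference label (low immunity at score 0.082); the
  originally published table prints that row's two label columns the other
  way around, an apparent transposition — either reading gives 9/10
  agreement.
* The tissue-mask pipeline is validated on synthetic rasters; real H&E
  thumbnails have pen marks, coverslip edges and tissue folds it has never
  seen.
* Scores compare across slides only insofar as `NumMax` is a stable
  within-slide anchor; a slide whose maximum patch is an artifact (e.g. a
  lymphoid follicle) will have depressed `a` values elsewhere.
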