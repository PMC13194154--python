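# tilscore

Interpretable immune-subtype prediction for lung adenocarcinoma from the
spatial distribution of tumor-infiltrating lymphocytes (TILs) on annotated
whole-slide images.

The tumor immune microenvironment splits LUAD tumors into "hot" tumors with
abundant lymphocyte infiltration and "cold" tumors without it — a
distinction that matters for immunotherapy decisions but is usually derived
from transcriptomics, which routine pathology labs do not have. `tilscore`
implements a transparent morphology-only classifier: given slide
annotations (tissue contours, tumor-parenchyma polygons and TIL detections,
e.g. exported from QuPath), it reduces each slide to a single interpretable
score and a binary subtype call. It is aimed at computational-pathology
researchers who have a cell-detection pipeline and want the downstream
spatial statistics, the classification rule, and its evaluation — without
any deep learning in the loop.

## The model

Each slide is tiled with non-overlapping 100 μm × 100 μm patches over the
tissue bounding box. Detections whose box center lies in stroma (inside a
tissue contour, outside all tumor parenchyma) are counted per patch, and
counts are normalized by the slide maximum:

```
a = Num / NumMax                      (relative lymphocyte density, 0–1)
```

Patches with `a > 0.2` are *high-attention* regions — foci of dense
lymphocyte aggregation; the empirical patch-density distribution is
bimodal, and the cutoff can be recalibrated by two-cluster Ward clustering
of the pooled `a` values. The per-slide **High-Aggregation TILs Patch Ratio
Score** is

```
Score = N_high / N_valid
```

where `N_valid` counts the patches inside tissue that contain at least one
counted TIL. A slide is called `Immunity_H` when `Score > 0.05`, else
`Immunity_L`; both inequalities are strict, and the score threshold can be
re-fit on labelled training slides by an accuracy-maximizing sweep.

Around this core the package provides: a seeded synthetic-slide generator
(Thomas-cluster + Poisson stromal point processes inside simulated
tissue/tumor geometry) so the whole pipeline is testable without WSIs; a
QuPath-style GeoJSON annotation reader/writer; a classical (non-learned)
tissue-mask pipeline (Roberts + Otsu + Canny(30, 120) + elliptical
closings); bilinear density heatmaps; diagnostic-accuracy statistics with
Wilson 95% CIs and Mann–Whitney AUC; and the IHC composite Z-score
reference standard (trimmed 10-field means, 0.2595 mm² HPF density
conversion, median dichotomization of the mean CD3/CD8/CD20/CD68 Z-score).

## Worked example

```python
import tilscore as t

# simulate a labelled cohort: 20 focally-clustered (hot) + 20 sparse (cold) slides
cohort = t.simulate_cohort(t.SyntheticCohortSpec(n_high=20, n_low=20, seed=17))
annotations = [ann for ann, _ in cohort]
reference   = [lab for _, lab in cohort]

model = t.TILSubtypeModel(annotations, labels=reference)
res = model.fit()                      # default thresholds: a > 0.2, Score > 0.05
cm, report = res.evaluate()
print(res.summary())
```

prints (abridged):

```
TIL Spatial Immune Subtype Model
==============================================
Slides:               40
Attention threshold:  a > 0.2
Score threshold:      Score > 0.05
Predicted Immunity_H: 20
Predicted Immunity_L: 20
Agreement with reference: 100.0%
----------------------------------------------
      slide_id  n_high  n_valid    score      label  reference
synthetic-H000     100      391 0.255754 Immunity_H Immunity_H
...
```

Every predicted label agrees with the simulated ground truth here; `score`
is the fraction of TIL-containing patches that are dense aggregation foci
(e.g. 0.256 = 100 of 391), which is what separates hot from cold slides.
The same pipeline runs from the shell:

```bash
tilscore simulate --n-high 5 --n-low 5 --seed 1 --out cohort/
tilscore score cohort/ --out results/ --labels cohort/labels.csv --heatmaps
tilscore demo        # the bundled ten-case example test set
```

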