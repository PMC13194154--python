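"""Rule-based immune subtype prediction from TIL spatial densities.

The model has two thresholds.  A patch whose normalized TIL density exceeds
the *attention threshold* (default 0.2) is a high-attention patch — a region
of focal, dense lymphocyte infiltration.  The per-slide High-Aggregation
TILs Patch Ratio Score is

    Score = N_high / N_valid,

the fraction of valid (TIL-containing, in-tissue) patches that are
high-attention; a slide is classified ``Immunity_H`` when Score exceeds the
*score threshold* (default 0.05), else ``Immunity_L``.  Both comparisons are
strict.

Both thresholds can be calibrated from training data: the attention
threshold by two-cluster Ward agglomerative clustering of the pooled 1-D
density values (the empirical patch-density distribution is bimodal — a
dense mass of sparse patches plus a sparser mass of dense patches), the
score threshold by sweeping candidate cutoffs against reference subtype
labels.  :class:`TILSubtypeModel` wraps calibration and scoring of a cohort
in a fit/results interface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .annotations import SlideAnnotation
from .grid import GridConfig, SlideGrid, quantify_slide

logger = logging.getLogger(__name__)

IMMUNITY_H = "Immunity_H"
IMMUNITY_L = "Immunity_L"

DEFAULT_ATTENTION_THRESHOLD = 0.2
DEFAULT_SCORE_THRESHOLD = 0.05


@dataclass(frozen=True)
class ModelConfig:
    """Decision thresholds of the subtype rule (both strict inequalities)."""

    attention_threshold: float = DEFAULT_ATTENTION_THRESHOLD
    score_threshold: float = DEFAULT_SCORE_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("attention_threshold", "score_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class SlideScore:
    """Per-slide score and predicted subtype label."""

    slide_id: str
    n_high: int
    n_valid: int
    score: float
    label: str
    degenerate: bool = False


def flag_high_attention(grid: SlideGrid, attention_threshold: float = DEFAULT_ATTENTION_THRESHOLD) -> SlideGrid:
    """Mark patches with ``a > threshold`` (strict) among valid patches."""
    if not 0.0 < attention_threshold < 1.0:
        raise ValueError(f"attention_threshold must lie in (0, 1), got {attention_threshold}")
    for p in grid.patches:
        if p.a is None:
            raise ValueError("densities not set; run normalize_density first")
        p.is_high_attention = bool(p.is_valid and p.a > attention_threshold)
    return grid


def compute_slide_score(grid: SlideGrid, score_threshold: float = DEFAULT_SCORE_THRESHOLD) -> SlideScore:
    """Score = N_high / N_valid; degenerate slides score 0 (Immunity_L)."""
    n_high = sum(p.is_high_attention for p in grid.patches)
    n_valid = sum(p.is_valid for p in grid.patches)
    score = n_high / n_valid if n_valid > 0 else 0.0
    return SlideScore(
        slide_id=grid.slide_id,
        n_high=n_high,
        n_valid=n_valid,
        score=score,
        label=classify_slide(score, score_threshold),
        degenerate=grid.degenerate,
    )


def classify_slide(score: float, score_threshold: float = DEFAULT_SCORE_THRESHOLD) -> str:
    """``Immunity_H`` iff score strictly exceeds the threshold."""
    return IMMUNITY_H if score > score_threshold else IMMUNITY_L


def score_slide(
    annotation: SlideAnnotation,
    grid_config: GridConfig | None = None,
    config: ModelConfig | None = None,
) -> SlideScore:
    """Full per-slide pipeline: grid, count, normalize, flag, score."""
    config = config or ModelConfig()
    grid = quantify_slide(annotation, grid_config)
    flag_high_attention(grid, config.attention_threshold)
    return compute_slide_score(grid, config.score_threshold)


def calibrate_attention_threshold(
    a_values: Sequence[float] | np.ndarray,
    *,
    min_gap: float = 0.02,
    max_values: int = 50_000,
    seed: int = 0,
) -> tuple[float, dict]:
    """Find the density cutoff separating the two modes of the a-distribution.

    Agglomerative clustering (Ward linkage, Euclidean, 1-D) cut at k=2; the
    threshold is the midpoint between the maximum of the lower cluster and
    the minimum of the upper one.  If the inter-cluster gap is narrower than
    ``min_gap`` the distribution is treated as unimodal and the field
    default 0.2 is returned with a warning.  Inputs larger than
    ``max_values`` are subsampled deterministically given ``seed``.

    Returns ``(threshold, diagnostics)`` where diagnostics carries the
    cluster sizes, boundary values and gap width.
    """
    a = np.asarray(a_values, dtype=float)
    if a.size < 10:
        raise ValueError(f"need at least 10 density values, got {a.size}")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("density values must lie in [0, 1]")
    if a.size > max_values:
        rng = np.random.default_rng(seed)
        a = rng.choice(a, size=max_values, replace=False)
    z = linkage(a.reshape(-1, 1), method="ward")
    labels = fcluster(z, t=2, criterion="maxclust")
    means = [a[labels == k].mean() for k in (1, 2)]
    lower, upper = (1, 2) if means[0] <= means[1] else (2, 1)
    lo_max = float(a[labels == lower].max())
    hi_min = float(a[labels == upper].min())
    gap = hi_min - lo_max
    diagnostics = {
        "n_lower": int((labels == lower).sum()),
        "n_upper": int((labels == upper).sum()),
        "lower_max": lo_max,
        "upper_min": hi_min,
        "gap": gap,
        "unimodal": gap < min_gap,
    }
    if gap < min_gap:
        warnings.warn(
            f"density distribution looks unimodal (gap {gap:.4f} < {min_gap}); "
            f"falling back to the default attention threshold {DEFAULT_ATTENTION_THRESHOLD}",
            stacklevel=2,
        )
        return DEFAULT_ATTENTION_THRESHOLD, diagnostics
    return (lo_max + hi_min) / 2.0, diagnostics


def calibrate_score_threshold(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str = IMMUNITY_H,
) -> tuple[float, pd.DataFrame]:
    """Choose the score cutoff maximizing training accuracy.

    Candidates are midpoints between consecutive sorted unique scores (plus
    guards below the minimum and above the maximum).  Ties on accuracy break
    first by Youden's J (sensitivity + specificity - 1), then by the
    smallest threshold.  Returns the chosen threshold and the full sweep
    table (threshold, accuracy, sensitivity, specificity, youden_j).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([lab == positive_label for lab in labels], dtype=bool)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 slides per class to calibrate")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate(([uniq[0] - np.spacing(1) if uniq[0] > 0 else uniq[0] / 2 - 1e-12], mids, [uniq[-1]]))
    rows = []
    for t in cands:
        pred = s > t
        tp = int((pred & y).sum())
        tn = int((~pred & ~y).sum())
        acc = (tp + tn) / len(s)
        sens = tp / n_pos
        spec = tn / n_neg
        rows.append((float(t), acc, sens, spec, sens + spec - 1.0))
    sweep = pd.DataFrame(rows, columns=["threshold", "accuracy", "sensitivity", "specificity", "youden_j"])
    best = sweep.sort_values(
        ["accuracy", "youden_j", "threshold"], ascending=[False, False, True], kind="stable"
    ).iloc[0]
    return float(best["threshold"]), sweep


class TILSubtypeModel:
    """Immune-subtype rule model over a cohort of annotated slides.

    Parameters
    ----------
    annotations
        Slide annotations (tissue/tumor polygons + TIL detections).
    labels
        Optional reference subtype labels (``Immunity_H`` / ``Immunity_L``),
        one per slide, used for threshold calibration and evaluation.
    grid_config, config
        Patch-grid and threshold settings; defaults are the field values
        (100 μm patches, a > 0.2, Score > 0.05).

    Examples
    --------
    >>> model = TILSubtypeModel(annotations, labels=reference)
    >>> res = model.fit()                        # default thresholds
    >>> res = model.fit(calibrate="score")       # tune Score cutoff on labels
    >>> print(res.summary())
    """

    def __init__(
        self,
        annotations: Sequence[SlideAnnotation],
        labels: Sequence[str] | None = None,
        grid_config: GridConfig | None = None,
        config: ModelConfig | None = None,
    ) -> None:
        if labels is not None and len(labels) != len(annotations):
            raise ValueError("labels must match annotations in length")
        self.annotations = list(annotations)
        self.labels = list(labels) if labels is not None else None
        self.grid_config = grid_config or GridConfig()
        self.config = config or ModelConfig()
        self._grids: list[SlideGrid] | None = None

    @property
    def grids(self) -> list[SlideGrid]:
        """Quantified slide grids (computed lazily, cached)."""
        if self._grids is None:
            self._grids = [quantify_slide(ann, self.grid_config) for ann in self.annotations]
        return self._grids

    def pooled_densities(self) -> np.ndarray:
        """All valid-patch a-values pooled across the cohort (calibration input)."""
        vals = [p.a for g in self.grids for p in g.patches if p.is_valid and p.a is not None]
        return np.asarray(vals, dtype=float)

    def fit(self, calibrate: str = "none", *, min_gap: float = 0.02, seed: int = 0) -> "TILSubtypeResults":
        """Score every slide; optionally calibrate thresholds first.

        ``calibrate`` is ``"none"`` (use configured thresholds),
        ``"attention"``, ``"score"`` (requires labels) or ``"both"``.
        """
        if calibrate not in ("none", "attention", "score", "both"):
            raise ValueError(f"unknown calibration mode {calibrate!r}")
        cfg = self.config
        diagnostics: dict = {}
        if calibrate in ("attention", "both"):
            thr, diag = calibrate_attention_threshold(self.pooled_densities(), min_gap=min_gap, seed=seed)
            cfg = replace(cfg, attention_threshold=thr)
            diagnostics["attention"] = diag
        scores = self._score_all(cfg)
        if calibrate in ("score", "both"):
            if self.labels is None:
                raise ValueError("score-threshold calibration requires reference labels")
            thr, sweep = calibrate_score_threshold([s.score for s in scores], self.labels)
            cfg = replace(cfg, score_threshold=thr)
            diagnostics["score_sweep"] = sweep
            scores = [
                replace(s, label=classify_slide(s.score, cfg.score_threshold)) for s in scores
            ]
        return TILSubtypeResults(self, cfg, scores, diagnostics)

    def _score_all(self, cfg: ModelConfig) -> list[SlideScore]:
        out = []
        for grid in self.grids:
            flag_high_attention(grid, cfg.attention_threshold)
            out.append(compute_slide_score(grid, cfg.score_threshold))
        return out


class TILSubtypeResults:
    """Fitted cohort scores, thresholds used, and evaluation helpers."""

    def __init__(
        self,
        model: TILSubtypeModel,
        config: ModelConfig,
        scores: list[SlideScore],
        diagnostics: dict,
    ) -> None:
        self.model = model
        self.config = config
        self.slide_scores = scores
        self.diagnostics = diagnostics

    @property
    def scores(self) -> pd.DataFrame:
        """Cohort score table: slide_id, n_high, n_valid, score, label."""
        df = pd.DataFrame(
            {
                "slide_id": [s.slide_id for s in self.slide_scores],
                "n_high": [s.n_high for s in self.slide_scores],
                "n_valid": [s.n_valid for s in self.slide_scores],
                "score": [s.score for s in self.slide_scores],
                "label": [s.label for s in self.slide_scores],
            }
        )
        if self.model.labels is not None:
            df["reference"] = self.model.labels
        return df

    @property
    def predicted_labels(self) -> list[str]:
        return [s.label for s in self.slide_scores]

    def evaluate(self, reference: Sequence[str] | None = None):
        """Diagnostic-accuracy report against reference labels (Wilson 95% CIs)."""
        from .metrics import classification_metrics, confusion_matrix, roc_auc

        ref = list(reference) if reference is not None else self.model.labels
        if ref is None:
            raise ValueError("no reference labels available")
        cm = confusion_matrix(self.predicted_labels, ref, positive_label=IMMUNITY_H)
        report = classification_metrics(cm)
        try:
            auc, _ = roc_auc([s.score for s in self.slide_scores], ref, positive_label=IMMUNITY_H)
            report = replace(report, auc=auc)
        except ValueError:
            pass
        return cm, report

    def summary(self) -> str:
        """Plain-text summary in the style of statistical results tables."""
        df = self.scores
        n_h = int((df["label"] == IMMUNITY_H).sum())
        lines = [
            "TIL Spatial Immune Subtype Model",
            "=" * 46,
            f"Slides:               {len(df)}",
            f"Attention threshold:  a > {self.config.attention_threshold:g}",
            f"Score threshold:      Score > {self.config.score_threshold:g}",
            f"Predicted Immunity_H: {n_h}",
            f"Predicted Immunity_L: {len(df) - n_h}",
        ]
        if "reference" in df.columns:
            acc = float((df["label"] == df["reference"]).mean())
            lines.append(f"Agreement with reference: {acc:.1%}")
        lines.append("-" * 46)
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.6f}"))
        return "\n".join(lines)
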