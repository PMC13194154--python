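"""IHC composite-score reference standard.

Immune cell densities are quantified by counting marker-positive cells
(CD3, CD8, CD20, CD68) in 10 randomly selected 400x high-power fields (HPF,
0.2595 mm² each) per case.  The highest and lowest field counts are
discarded and the remaining fields averaged; the trimmed mean is converted
to a density (cells/mm²).  Per marker, densities are Z-score normalized
across the cohort; the composite IHC score of a case is the mean of its
four marker Z-scores, and cases above the cohort median composite (strict)
are labelled IHC-high immunity.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKERS = ("CD3", "CD8", "CD20", "CD68")
HPF_AREA_MM2 = 0.2595

IHC_HIGH = "high"
IHC_LOW = "low"


def trimmed_field_mean(counts: Sequence[float]) -> float:
    """Mean field count after removing one maximum and one minimum.

    Exactly one occurrence of the maximum and one of the minimum are
    excluded (a constant list therefore keeps its value); at least 3 counts
    are required.
    """
    c = sorted(float(v) for v in counts)
    if len(c) < 3:
        raise ValueError(f"need at least 3 field counts, got {len(c)}")
    return float(np.mean(c[1:-1]))


def density_per_mm2(mean_count: float, hpf_area_mm2: float = HPF_AREA_MM2) -> float:
    """Convert a mean per-field count to cells/mm² of the field area."""
    if hpf_area_mm2 <= 0:
        raise ValueError("hpf_area_mm2 must be positive")
    if mean_count < 0:
        raise ValueError("mean_count must be non-negative")
    return mean_count / hpf_area_mm2


def composite_ihc_scores(
    field_counts: pd.DataFrame,
    hpf_area_mm2: float = HPF_AREA_MM2,
) -> pd.DataFrame:
    """Per-case composite Z-scores and median-split immunity labels.

    Parameters
    ----------
    field_counts
        Long table with columns ``case_id``, ``marker``, ``count`` (one row
        per counted field); every case must carry all four markers with at
        least 3 fields each.

    Returns
    -------
    DataFrame indexed by case with per-marker densities (``density_CD3``
    ...), per-marker Z-scores (``z_CD3`` ...), ``composite`` and
    ``ihc_label`` (``high`` iff composite strictly exceeds the cohort
    median).

    Z-scores use the sample SD (n-1).  A marker whose density is constant
    across the cohort has undefined Z-scores; they are set to 0 with a
    warning rather than erroring the whole panel.
    """
    required = {"case_id", "marker", "count"}
    if not required.issubset(field_counts.columns):
        raise ValueError(f"field_counts needs columns {sorted(required)}")
    cases = field_counts["case_id"].unique()
    if len(cases) < 2:
        raise ValueError("need at least 2 cases for cohort Z-scores")

    rows = {}
    for case_id, case_df in field_counts.groupby("case_id", sort=False):
        markers = set(case_df["marker"])
        if not set(MARKERS).issubset(markers):
            missing = set(MARKERS) - markers
            raise ValueError(f"case {case_id} missing markers: {sorted(missing)}")
        rows[case_id] = {
            f"density_{m}": density_per_mm2(
                trimmed_field_mean(case_df.loc[case_df["marker"] == m, "count"]), hpf_area_mm2
            )
            for m in MARKERS
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "case_id"

    for m in MARKERS:
        dens = out[f"density_{m}"]
        sd = dens.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            logger.warning("marker %s has zero density SD across cohort; Z set to 0", m)
            out[f"z_{m}"] = 0.0
        else:
            out[f"z_{m}"] = (dens - dens.mean()) / sd
    out["composite"] = out[[f"z_{m}" for m in MARKERS]].mean(axis=1)
    median = out["composite"].median()
    out["ihc_label"] = np.where(out["composite"] > median, IHC_HIGH, IHC_LOW)
    return out


def compare_marker_groups(
    field_counts: pd.DataFrame,
    labels: pd.Series,
    hpf_area_mm2: float = HPF_AREA_MM2,
) -> pd.DataFrame:
    """Two-group marker summary (mean ± SD per group, Welch t and rank tests).

    Thin reporting helper for tables comparing marker counts between
    predicted immunity groups; ``labels`` maps case_id to a group name.
    """
    from scipy import stats

    panels = composite_ihc_scores(field_counts, hpf_area_mm2)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    rows = []
    for m in MARKERS:
        dens = panels[f"density_{m}"] * hpf_area_mm2  # back to counts/field for reporting
        g0 = dens[labels.reindex(dens.index) == groups[0]]
        g1 = dens[labels.reindex(dens.index) == groups[1]]
        t_p = stats.ttest_ind(g0, g1, equal_var=False).pvalue
        u_p = stats.mannwhitneyu(g0, g1).pvalue
        rows.append(
            {
                "marker": m,
                f"mean_{groups[0]}": g0.mean(),
                f"sd_{groups[0]}": g0.std(ddof=1),
                f"mean_{groups[1]}": g1.mean(),
                f"sd_{groups[1]}": g1.std(ddof=1),
                "t_pvalue": t_p,
                "rank_pvalue": u_p,
            }
        )
    return pd.DataFrame(rows).set_index("marker")
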