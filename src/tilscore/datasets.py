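"""Bundled example data.

``EXAMPLE_VALIDATION_CASES`` is a published ten-case lung-adenocarcinoma
test set: per-case high-attention patch ratio scores together with the
transcriptomically derived reference subtype.  One borderline case
(TCGA-44-2661, score 0.082299) is transcriptomically low-immunity despite a
score above the 0.05 decision threshold, so the rule misclassifies exactly
that case (9/10 agreement).

``EXTERNAL_VALIDATION_CM`` is the external-cohort confusion matrix of the
same model evaluated against an IHC composite-score reference in 60 cases
(positive class = high immunity).
"""

from __future__ import annotations

import pandas as pd

from .metrics import ConfusionMatrix

# (case_id, score, transcriptomic reference label)
EXAMPLE_VALIDATION_CASES: list[tuple[str, float, str]] = [
    ("TCGA-55-6979-01Z-00-DX1", 0.025260, "Immunity_L"),
    ("TCGA-55-6975-01Z-00-DX1", 0.015157, "Immunity_L"),
    ("TCGA-55-6972-01Z-00-DX1", 0.005871, "Immunity_L"),
    ("TCGA-44-5645-01Z-00-DX1", 0.058781, "Immunity_H"),
    ("TCGA-44-6778-01Z-00-DX1", 0.053232, "Immunity_H"),
    ("TCGA-44-2665-01Z-00-DX1", 0.042932, "Immunity_L"),
    ("TCGA-44-3398-01Z-00-DX1", 0.034461, "Immunity_L"),
    ("TCGA-44-2661-01Z-00-DX1", 0.082299, "Immunity_L"),
    ("TCGA-49-4490-01Z-00-DX1", 0.020078, "Immunity_L"),
    ("TCGA-44-6145-01Z-00-DX1", 0.064477, "Immunity_H"),
]

EXTERNAL_VALIDATION_CM = ConfusionMatrix(tp=26, fp=2, fn=4, tn=28)


def example_score_table() -> pd.DataFrame:
    """The example test set as a DataFrame (case_id, score, reference)."""
    return pd.DataFrame(EXAMPLE_VALIDATION_CASES, columns=["case_id", "score", "reference"])
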