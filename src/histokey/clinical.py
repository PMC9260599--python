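"""Oral lichen planus sign score and treatment-response label.

Eleven oral sites (lips, cheeks, gums, tongue halves, floor of mouth,
palates) are each scored 0/1/2 for three lesion types — reticulation/
patch, erythema/congestion, erosion/ulcer — where 0 = absent, 1 = present
on at most half the site, 2 = more than half.  The total score weights
erythema 1.5x and erosion 2x:

    total = sum over sites (reticulation + 1.5 * erythema + 2 * erosion)

giving a range of 0 to 99.  Treatment is "effective" when the score at
the third visit is strictly more than 10% below the first visit's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "LESION_TYPES",
    "ClinicalAssessment",
    "total_score",
    "response_label",
    "read_assessments",
]

SITES = (
    "upper lip", "lower lip", "left cheek", "right cheek",
    "maxillary gum", "mandibular gum", "left tongue", "right tongue",
    "floor of mouth", "hard palate", "soft palate",
)
LESION_TYPES = ("reticulation", "erythema", "erosion")
LESION_WEIGHTS: Mapping[str, float] = {"reticulation": 1.0, "erythema": 1.5, "erosion": 2.0}
MAX_SCORE = len(SITES) * 2 * sum(LESION_WEIGHTS.values())  # 99


@dataclass
class ClinicalAssessment:
    """One visit's 11-site x 3-type extent scores for a patient."""

    patient_id: str
    visit: int
    scores: pd.DataFrame = field(default=None)  # index SITES, columns LESION_TYPES

    def __post_init__(self):
        if self.scores is None:
            self.scores = pd.DataFrame(0, index=list(SITES), columns=list(LESION_TYPES))
        self.scores = self.scores.reindex(index=list(SITES), columns=list(LESION_TYPES))
        if self.scores.isna().any().any():
            raise ValueError(
                f"assessment for {self.patient_id} visit {self.visit} is missing entries"
            )
        values = self.scores.to_numpy()
        if not np.isin(values, (0, 1, 2)).all():
            raise ValueError("site extent scores must be in {0, 1, 2}")


def total_score(a: ClinicalAssessment) -> float:
    """Weighted total sign score, in [0, 99]."""
    w = np.array([LESION_WEIGHTS[t] for t in LESION_TYPES])
    return float((a.scores.to_numpy() * w[None, :]).sum())


def response_label(visit1: ClinicalAssessment, visit3: ClinicalAssessment) -> int:
    """1 (effective) iff the visit-3 score is >10% below the visit-1 score."""
    if visit1.patient_id != visit3.patient_id:
        raise ValueError(
            f"assessments belong to different patients: "
            f"{visit1.patient_id!r} vs {visit3.patient_id!r}"
        )
    s1, s3 = total_score(visit1), total_score(visit3)
    if s1 == 0:
        raise ValueError(
            f"patient {visit1.patient_id}: baseline score is 0, relative change undefined"
        )
    return int(s3 < 0.9 * s1)


def read_assessments(path: str) -> dict[tuple[str, int], ClinicalAssessment]:
    """Read per-visit assessments from a long CSV.

    Columns: patient_id, visit, site, reticulation, erythema, erosion.
    Returns a dict keyed by (patient_id, visit).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "visit", "site", *LESION_TYPES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assessment file missing columns: {sorted(missing)}")
    out = {}
    for (pid, visit), grp in df.groupby(["patient_id", "visit"]):
        scores = grp.set_index("site")[list(LESION_TYPES)]
        out[(pid, int(visit))] = ClinicalAssessment(
            patient_id=pid, visit=int(visit), scores=scores
        )
    return out
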