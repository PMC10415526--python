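"""Subject records: fatigue scores, grouping and clinical covariates.

Trait fatigue is measured with the 7-item Fatigue Severity Scale (FSS-7),
a mean score on [1, 7]; a score strictly greater than 4 defines the
high-fatigue group.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import pandas as pd

__all__ = ["SubjectRecord", "classify_fatigue", "subjects_to_frame",
           "subjects_from_frame"]


def classify_fatigue(fss7: float) -> str:
    """Fatigue group from the FSS-7 score: 'high' iff fss7 > 4, else 'low'."""
    if not 1.0 <= fss7 <= 7.0:
        raise ValueError(f"FSS-7 score must lie in [1, 7], got {fss7}")
    return "high" if fss7 > 4.0 else "low"


@dataclass
class SubjectRecord:
    """One participant's fatigue, demographic and stroke characteristics.

    ``grip_pct`` and ``nhpt_pct`` are percentages of the unaffected hand;
    HADS depression is capped at 11 by the inclusion criteria.
    """

    id: str
    fss7: float
    fatigue_group: str
    sex: str
    age: float
    grip_pct: float
    nhpt_pct: float
    hads_anx: float
    hads_dep: float
    hemisphere_affected: str
    stroke_type: str
    time_post_stroke: float
    vascular_territory: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fatigue_group != classify_fatigue(self.fss7):
            raise ValueError(
                f"subject {self.id}: group {self.fatigue_group!r} inconsistent "
                f"with FSS-7 = {self.fss7} (high iff > 4)"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.hads_dep > 11:
            raise ValueError("HADS depression > 11 violates inclusion criteria")


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in subjects])


def subjects_from_frame(frame: pd.DataFrame) -> list[SubjectRecord]:
    recs = []
    for row in frame.to_dict(orient="records"):
        if pd.isna(row.get("vascular_territory")):
            row["vascular_territory"] = None
        recs.append(SubjectRecord(**row))
    return recs
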