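"""Adjudication bookkeeping: causality, severity, organ systems, reviewer flow.

Two junior reviewers assess each trigger-positive case independently; on
disagreement the senior panel decides. Causality follows the six WHO-UMC
levels; harm severity follows the NCC MERP A-I ladder, where grades E-I
count as harm (grade D - abnormality requiring monitoring but no harm - is
retained for reporting). This module records human verdicts and summarizes
them; it never infers causality itself.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, model_validator

from ._utils import percent

__all__ = [
    "CausalityLevel",
    "SeverityGrade",
    "ORGAN_SYSTEMS",
    "AdeRecord",
    "ReviewDecision",
    "EscalationRequiredError",
    "reconcile",
    "summarize_severity",
    "summarize_causality",
    "summarize_organ_systems",
]


class CausalityLevel(str, enum.Enum):
    """WHO-UMC drug-event causality, strongest to weakest."""

    definitely_related = "definitely_related"
    very_probably_related = "very_probably_related"
    probably_related = "probably_related"
    probably_not_related = "probably_not_related"
    to_be_evaluated = "to_be_evaluated"
    not_evaluable = "not_evaluable"


class SeverityGrade(str, enum.Enum):
    """NCC MERP medication-error grades A (potential) through I (death)."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"
    H = "H"
    I = "I"

    @property
    def is_harm(self) -> bool:
        """Grades E-I are the harm subset used in detection analyses."""
        return self.value in "EFGHI"


#: The nine organ-system groups of the ADE taxonomy, heaviest first in the
#: source cohort (blood 46, GI 38, liver/kidney 21, ...).
ORGAN_SYSTEMS: tuple[str, ...] = (
    "blood_bleeding_clotting",
    "gastrointestinal",
    "liver_kidney",
    "systemic",
    "metabolic_nutritional",
    "other",
    "nervous_system",
    "skin_adnexa",
    "musculoskeletal",
)


class AdeRecord(BaseModel):
    """One adjudicated adverse drug event."""

    patient_id: str
    description: str = ""
    implicated_drug: str = ""
    organ_system: str
    causality: CausalityLevel
    severity: SeverityGrade
    supporting_trigger_id: Optional[str] = None  # None for false-negative discoveries

    @model_validator(mode="after")
    def _check_organ(self) -> "AdeRecord":
        if self.organ_system not in ORGAN_SYSTEMS:
            raise ValueError(
                f"organ_system {self.organ_system!r} not in the nine-group taxonomy"
            )
        return self


class EscalationRequiredError(ValueError):
    """Junior reviewers disagree and no senior verdict was supplied."""


class ReviewDecision(BaseModel):
    case_id: str
    junior_1: bool
    junior_2: bool
    senior_panel: Optional[bool] = None
    final: bool

    @model_validator(mode="after")
    def _check_flow(self) -> "ReviewDecision":
        if self.junior_1 != self.junior_2:
            if self.senior_panel is None:
                raise ValueError(f"case {self.case_id}: disagreement without senior verdict")
            if self.final != self.senior_panel:
                raise ValueError(f"case {self.case_id}: final must follow the senior panel")
        elif self.final != self.junior_1:
            raise ValueError(f"case {self.case_id}: final must follow the agreed junior verdict")
        return self


def reconcile(
    junior_1: bool, junior_2: bool, senior_panel: Optional[bool] = None
) -> bool:
    """Final ADE verdict: junior agreement stands; disagreement goes to seniors.

    Symmetric in the two junior verdicts. Raises
    :class:`EscalationRequiredError` when the juniors disagree and no senior
    verdict is available.
    """
    if junior_1 == junior_2:
        return junior_1
    if senior_panel is None:
        raise EscalationRequiredError("junior reviewers disagree; senior panel verdict required")
    return senior_panel


def _tabulate(labels: Iterable[str], order: Sequence[str] | None = None) -> pd.DataFrame:
    counts = Counter(labels)
    total = sum(counts.values())
    if order is None:
        keys = [k for k, _ in counts.most_common()]
    else:
        keys = [k for k in order if k in counts]
    rows = [
        {"level": k, "count": counts[k], "pct": percent(counts[k], total)} for k in keys
    ]
    return pd.DataFrame(rows, columns=["level", "count", "pct"])


def summarize_severity(ades: Sequence[AdeRecord]) -> pd.DataFrame:
    """Counts and percentages by NCC MERP grade (A..I order, observed grades)."""
    if not ades:
        return pd.DataFrame(columns=["level", "count", "pct"])
    return _tabulate((a.severity.value for a in ades), order=[g.value for g in SeverityGrade])


def summarize_causality(ades: Sequence[AdeRecord]) -> pd.DataFrame:
    """Counts and percentages by WHO-UMC level, strongest first."""
    if not ades:
        return pd.DataFrame(columns=["level", "count", "pct"])
    return _tabulate(
        (a.causality.value for a in ades), order=[c.value for c in CausalityLevel]
    )


def summarize_organ_systems(ades: Sequence[AdeRecord]) -> pd.DataFrame:
    """Counts and percentages by organ-system group, descending count."""
    if not ades:
        return pd.DataFrame(columns=["level", "count", "pct"])
    df = _tabulate(a.organ_system for a in ades)
    return df.sort_values(["count", "level"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )
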