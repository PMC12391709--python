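"""Detection-performance metrics for trigger-tool ADE surveillance.

Definitions (all percentages rounded half-up to two decimals, matching the
conventional printed style):

* PPV = true positives / positives x 100%, per trigger and overall; the
  overall PPV pools counts (sum ADEs / sum positives), it is not a mean of
  per-trigger PPVs.
* Sensitivity/specificity are patient-level: trigger-positive status against
  adjudicated ADE status. The "Correctness Index" is Youden's J =
  sensitivity + specificity - 1 on the fractional scale.
* Rates: ADEs per 1,000 patient-days (ADEs / total patient-days x 1000),
  per 100 patients (ADEs / patients x 100), and the per-"1,000 drugs" figure,
  whose published formula divides by the summed count of medication types per
  case and multiplies by 100 (the naming inconsistency is preserved
  deliberately; see docs/methods.md).
* Undefined ratios (zero denominators) surface as None, never as silent 0.
"""

from __future__ import annotations

import enum
import json
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from ._utils import percent, round_half_up
from .adjudication import AdeRecord
from .records import HospitalizationRecord, length_of_stay
from .trigger_engine import ScreeningResult

__all__ = [
    "ConfusionMatrix",
    "TriggerUtility",
    "MetricsReport",
    "ppv",
    "confusion_metrics",
    "ade_rates",
    "prevalence",
    "classify_utility",
    "build_report",
]


class ConfusionMatrix(BaseModel):
    """Patient-level 2x2: trigger-positive status x adjudicated ADE status."""

    tp: int = Field(ge=0)
    fp: int = Field(ge=0)
    fn: int = Field(ge=0)
    tn: int = Field(ge=0)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class TriggerUtility(str, enum.Enum):
    high = "high"
    moderate = "moderate"
    low = "low"


def ppv(positives: int, true_ades: int) -> Optional[float]:
    """Positive predictive value in percent; None when no positives exist."""
    if true_ades < 0 or positives < 0:
        raise ValueError("counts must be nonnegative")
    if true_ades > positives:
        raise ValueError(f"true ADEs ({true_ades}) exceed positives ({positives})")
    if positives == 0:
        return None
    return percent(true_ades, positives)


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Sensitivity %, specificity %, and Youden's J from a patient-level 2x2.

    Either margin being empty yields None for the affected metrics.
    """
    sens = spec = youden = None
    if cm.tp + cm.fn > 0:
        sens = percent(cm.tp, cm.tp + cm.fn)
    if cm.tn + cm.fp > 0:
        spec = percent(cm.tn, cm.tn + cm.fp)
    if sens is not None and spec is not None:
        youden = round_half_up(sens / 100.0 + spec / 100.0 - 1.0, 2)
    return {"sensitivity": sens, "specificity": spec, "youden": youden}


def ade_rates(
    n_ades: int,
    total_patient_days: int,
    n_patients: int,
    total_medication_types: int,
) -> dict[str, float]:
    """The three published ADE occurrence rates.

    ``total_medication_types`` is the cohort sum of per-case medication-type
    counts; the published "per 1,000 drugs" formula multiplies by 100.
    """
    if min(total_patient_days, n_patients, total_medication_types) <= 0:
        raise ZeroDivisionError("rate denominators must be positive")
    return {
        "per_1000_patient_days": round_half_up(1000.0 * n_ades / total_patient_days, 2),
        "per_100_patients": round_half_up(100.0 * n_ades / n_patients, 2),
        "per_1000_drugs": round_half_up(100.0 * n_ades / total_medication_types, 2),
    }


def prevalence(n_ade_patients: int, n_patients: int) -> float:
    """Percent of patients with at least one adjudicated ADE."""
    return percent(n_ade_patients, n_patients)


def classify_utility(
    ppv_pct: Optional[float], high_cut: float = 50.0, low_cut: float = 20.0
) -> Optional[TriggerUtility]:
    """Utility class from a trigger's PPV: high >= 50%, low < 20%, else moderate."""
    if ppv_pct is None:
        return None
    if ppv_pct >= high_cut:
        return TriggerUtility.high
    if ppv_pct < low_cut:
        return TriggerUtility.low
    return TriggerUtility.moderate


class MetricsReport(BaseModel):
    per_trigger: dict[str, dict]  # trigger_id -> positives / true_ades / ppv / utility
    overall_ppv: Optional[float]
    confusion: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    youden: Optional[float]
    prevalence: float
    false_negative_rate: Optional[float]
    rate_per_1000_patient_days: float
    rate_per_100_patients: float
    rate_per_1000_drugs: float
    n_patients: int
    n_ades: int
    n_trigger_instances: int

    def per_trigger_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trigger_id": tid,
                "positives": d["positives"],
                "true_ades": d["true_ades"],
                "ppv": d["ppv"],
                "utility": d["utility"],
            }
            for tid, d in sorted(self.per_trigger.items())
        ]
        return pd.DataFrame(rows, columns=["trigger_id", "positives", "true_ades", "ppv", "utility"])

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.model_dump(mode="json"), **kwargs)


def build_report(
    screening: ScreeningResult,
    ades: Sequence[AdeRecord],
    cohort: Sequence[HospitalizationRecord],
) -> MetricsReport:
    """Assemble the full metric set from screening output and adjudicated ADEs.

    The medication-type denominator is the summed count of distinct targeted
    drug classes per case. ADE patient status comes from the adjudicated
    records; an ADE without a supporting trigger is a false-negative
    discovery and contributes to the FN cell.
    """
    cohort_ids = {r.patient_id for r in cohort}
    for a in ades:
        if a.patient_id not in cohort_ids:
            raise ValueError(f"ADE for unknown patient {a.patient_id!r}")
    for pid in screening.per_patient_flag:
        if pid not in cohort_ids:
            raise ValueError(f"screening flag for unknown patient {pid!r}")

    per_trigger_pos = screening.positives_per_trigger()
    per_trigger_true: dict[str, int] = {}
    for a in ades:
        if a.supporting_trigger_id is not None:
            per_trigger_true[a.supporting_trigger_id] = (
                per_trigger_true.get(a.supporting_trigger_id, 0) + 1
            )

    per_trigger = {}
    for tid in sorted(set(per_trigger_pos) | set(per_trigger_true)):
        pos = per_trigger_pos.get(tid, 0)
        true = per_trigger_true.get(tid, 0)
        p = ppv(pos, true)
        per_trigger[tid] = {
            "positives": pos,
            "true_ades": true,
            "ppv": p,
            "utility": classify_utility(p).value if p is not None else None,
        }

    total_pos = sum(per_trigger_pos.values())
    total_true = sum(per_trigger_true.values())
    overall = ppv(total_pos, total_true) if total_pos else None

    ade_patients = {a.patient_id for a in ades}
    flagged = {pid for pid, f in screening.per_patient_flag.items() if f}
    unflagged = cohort_ids - flagged
    cm = ConfusionMatrix(
        tp=len(flagged & ade_patients),
        fp=len(flagged - ade_patients),
        fn=len(unflagged & ade_patients),
        tn=len(unflagged - ade_patients),
    )
    conf = confusion_metrics(cm)
    fnr = percent(cm.fn, cm.fn + cm.tn) if (cm.fn + cm.tn) > 0 else None

    patient_days = sum(length_of_stay(r) for r in cohort)
    med_types = sum(len(r.target_drug_classes) for r in cohort)
    rates = ade_rates(len(ades), patient_days, len(cohort), med_types)

    return MetricsReport(
        per_trigger=per_trigger,
        overall_ppv=overall,
        confusion=cm,
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        youden=conf["youden"],
        prevalence=prevalence(len(ade_patients), len(cohort)),
        false_negative_rate=fnr,
        rate_per_1000_patient_days=rates["per_1000_patient_days"],
        rate_per_100_patients=rates["per_100_patients"],
        rate_per_1000_drugs=rates["per_1000_drugs"],
        n_patients=len(cohort),
        n_ades=len(ades),
        n_trigger_instances=screening.n_instances,
    )
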