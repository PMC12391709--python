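import datetime as dt

import pytest

from pahgtt.records import (
    ClinicalEvent,
    HospitalizationRecord,
    InterventionEvent,
    LabObservation,
    MedicationExposure,
)

ADMISSION = dt.date(2022, 3, 1)


def ts(day: int = 1, hour: int = 12) -> dt.datetime:
    return dt.datetime.combine(ADMISSION + dt.timedelta(days=day), dt.time(hour, 0))


def lab(analyte: str, value: float, day: int = 1, hour: int = 12) -> LabObservation:
    return LabObservation(analyte=analyte, value=value, timestamp=ts(day, hour))


def med(
    name: str,
    day: int = 1,
    duration_h: int = 12,
    target: bool = False,
    abrupt: bool = False,
    drug_class: str = "",
) -> MedicationExposure:
    start = ts(day, 8)
    return MedicationExposure(
        drug_name=name,
        drug_class=drug_class,
        start=start,
        stop=start + dt.timedelta(hours=max(duration_h, 25 if target else duration_h)),
        is_target_pah_drug=target,
        stopped_abruptly=abrupt,
    )


def event(term: str, day: int = 1) -> ClinicalEvent:
    return ClinicalEvent(term=term, timestamp=ts(day))


def intervention(kind: str, day: int = 1) -> InterventionEvent:
    return InterventionEvent(kind=kind, timestamp=ts(day))


def make_record(
    patient_id: str = "P001",
    age: float = 30.0,
    sex: str = "female",
    los_days: int = 7,
    n_comorbidities: int = 3,
    n_prior: int = 2,
    target_classes: frozenset[str] | set[str] = frozenset({"pah_sildenafil"}),
    labs=(),
    medications=(),
    events=(),
    interventions=(),
) -> HospitalizationRecord:
    """Minimal valid admission; a sildenafil exposure is added automatically."""
    meds = list(medications)
    if not any(m.is_target_pah_drug for m in meds):
        meds.append(med("sildenafil", day=0, target=True, drug_class="pah_sildenafil"))
    return HospitalizationRecord(
        patient_id=patient_id,
        age_at_admission=age,
        sex=sex,
        admission_date=ADMISSION,
        discharge_date=ADMISSION + dt.timedelta(days=los_days),
        n_comorbidities=n_comorbidities,
        n_prior_hospitalizations=n_prior,
        target_drug_classes=frozenset(target_classes),
        labs=list(labs),
        medications=meds,
        events=list(events),
        interventions=list(interventions),
    )


@pytest.fixture
def record_factory():
    return make_record
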