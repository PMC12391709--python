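"""Independent brute-force re-implementation of the 24 trigger rules.

Deliberately naive (plain scans, no shared code with the engine) so it can
serve as an oracle for equivalence tests on small cohorts.
"""

from __future__ import annotations

from pahgtt.records import HospitalizationRecord

_A_CLASS_DRUGS = {
    "A1": {"norepinephrine", "dobutamine", "mesalamine", "ephedrine", "dopamine", "phenylephrine"},
    "A2": {"metoclopramide", "tropisetron", "dolasetron", "palonosetron", "ondansetron",
           "fosaprepitant", "aprepitant", "phenformin"},
    "A3": {"montmorillonite powder", "bifidobacterium bifidum tetragonum",
           "live combined bifidobacterium and lactobacillus tablets",
           "bifidobacterium live bacteria", "loperamide", "saccharomyces boulardii",
           "live bacillus cereus bifidus"},
    "A4": {"glutathione", "diammonium glycyrrhizinate", "magnesium isoglycyrrhizinate",
           "complex glycyrrhizin", "monoammonium cysteine glycyrrhizinate",
           "polyenylphosphatidylcholine", "ursodeoxycholic acid", "silymarin"},
    "A5": {"glycerine enema", "lactulose oral solution", "lactulose", "hemp nut soft gels",
           "bisacodyl enteric tablets", "bisacodyl", "senna"},
    "A6": {"loratadine", "ebastine", "chlorpheniramine maleate", "olopatadine", "cetirizine",
           "cyproheptadine", "promethazine", "diphenhydramine"},
}

_S_GROUP_TERMS = {
    "S1": {"rectal_bleeding", "nosebleed", "eye_bleeding", "intra_abdominal_bleeding",
           "hemorrhage", "bleeding_tendency", "severe_bleeding", "vomiting_blood",
           "gastrointestinal_bleeding", "subcutaneous_bleeding", "urinary_tract_bleeding"},
    "S2": {"nausea", "vomiting", "abdominal_pain", "diarrhea", "bloating"},
    "S3": {"arthralgia", "bone_pain", "jaw_pain", "back_pain", "neck_pain", "chest_pain"},
    "S4": {"flushing", "hot_flushes", "rash", "itching", "hives", "eczema"},
    "S5": {"peripheral_edema", "edema", "swelling", "angioedema", "lower_extremity_edema",
           "fluid_retention", "retinal_edema", "facial_edema"},
    "S6": {"dizziness", "headache"},
    "S7": {"insomnia", "anxiety", "transient_amnesia", "depression", "drowsiness", "vertigo",
           "upright_vertigo", "fainting", "loss_of_consciousness", "numbness",
           "floating_sensation", "neuralgia", "neuropathy"},
    "S8": {"kidney_injury", "acute_kidney_injury", "oliguria", "anuria",
           "acute_tubular_necrosis", "tubular_dysfunction", "proteinuria", "hematuria",
           "chronic_kidney_damage"},
}


def _hb_bound(age: float, sex: str):
    if 0.5 <= age < 5:
        return 110.0
    if 5 <= age < 12:
        return 115.0
    if 12 <= age < 15:
        return 120.0
    if age >= 15:
        return 120.0 if sex == "male" else 110.0
    return None


def brute_force_triggers(rec: HospitalizationRecord) -> set[str]:
    hits: set[str] = set()
    labs = [(l.analyte.value, l.value, l.timestamp) for l in rec.labs]

    def vals(a):
        return [v for (an, v, _) in labs if an == a]

    if any(v > 0.3 for v in vals("eosinophils_abs")):
        hits.add("L1")
    if any(v < 50 for v in vals("platelets")):
        hits.add("L2")
    if any(v < 3 for v in vals("leukocytes")):
        hits.add("L3")
    bili_up = any(v > 2 * 21.0 for v in vals("total_bilirubin"))
    alp_up = any(v > 2 * 125.0 for v in vals("alp"))
    if (
        any(v > 3 * 40.0 for v in vals("alt"))
        or any(v > 3 * 40.0 for v in vals("ast"))
        or (bili_up and alp_up)
    ):
        hits.add("L4")
    for analyte in ("bun", "creatinine"):
        series = sorted(((t, v) for (an, v, t) in labs if an == analyte))
        if len(series) >= 2 and series[0][1] > 0:
            if any(v > 2 * series[0][1] for _, v in series[1:]):
                hits.add("L5")
    bound = _hb_bound(rec.age_at_admission, rec.sex.value)
    if bound is not None and any(v < bound for v in vals("hemoglobin")):
        hits.add("L6")
    if any(v > 145 for v in vals("sodium")):
        hits.add("L7")

    for tid, names in _A_CLASS_DRUGS.items():
        for m in rec.medications:
            if not m.is_target_pah_drug and m.drug_name.strip().lower() in names:
                hits.add(tid)
    for tid, terms in _S_GROUP_TERMS.items():
        for e in rec.events:
            if e.term in terms:
                hits.add(tid)
    for iv in rec.interventions:
        hits.add("T1" if iv.kind.value == "icu_transfer" else "T2")
    if any(m.is_target_pah_drug and m.stopped_abruptly for m in rec.medications):
        hits.add("T3")
    return hits
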