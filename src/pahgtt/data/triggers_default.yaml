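# Default trigger rule set: 24 triggers for ADE surveillance in hospitalized
# PAH patients (7 laboratory, 6 antidote, 8 symptom, 3 treatment).
# All printed thresholds are strict inequalities. Upper-limit-of-normal (ULN)
# values are site-configurable here; thresholds expressed as `uln_multiple`
# are resolved against this table at load time.
uln:
  alt: 40.0              # U/L
  ast: 40.0              # U/L
  total_bilirubin: 21.0  # umol/L
  alp: 125.0             # U/L

triggers:
  - id: L1
    category: laboratory
    description: "Absolute eosinophils > 0.3 x 10^9/L"
    condition:
      shape: threshold
      analyte: eosinophils_abs
      comparator: ">"
      bound: 0.3
  - id: L2
    category: laboratory
    description: "Platelet count < 50 x 10^9/L"
    condition:
      shape: threshold
      analyte: platelets
      comparator: "<"
      bound: 50.0
  - id: L3
    category: laboratory
    description: "Leucocyte count < 3 x 10^9/L"
    condition:
      shape: threshold
      analyte: leukocytes
      comparator: "<"
      bound: 3.0
  - id: L4
    category: laboratory
    description: >-
      ALT or AST > 3x ULN, or total bilirubin and ALP both > 2x ULN
    condition:
      shape: composite
      op: any
      parts:
        - {shape: threshold, analyte: alt, comparator: ">", uln_multiple: 3.0}
        - {shape: threshold, analyte: ast, comparator: ">", uln_multiple: 3.0}
        - shape: composite
          op: all
          parts:
            - {shape: threshold, analyte: total_bilirubin, comparator: ">", uln_multiple: 2.0}
            - {shape: threshold, analyte: alp, comparator: ">", uln_multiple: 2.0}
  - id: L5
    category: laboratory
    description: "BUN or serum creatinine > 2x the baseline (first in-stay) level"
    condition:
      shape: baseline_ratio
      analytes: [bun, creatinine]
      ratio: 2.0
  - id: L6
    category: laboratory
    description: >-
      Hemoglobin below the age/sex band: 6 mo-5 y < 110, 5-12 y < 115,
      12-15 y < 120, males > 15 y < 120, females > 15 y < 110 g/L
    condition:
      shape: threshold
      analyte: hemoglobin
      comparator: "<"
      strata:
        - {age_min: 0.5, age_max: 5.0, bound: 110.0}
        - {age_min: 5.0, age_max: 12.0, bound: 115.0}
        - {age_min: 12.0, age_max: 15.0, bound: 120.0}
        - {age_min: 15.0, sex: male, bound: 120.0}
        - {age_min: 15.0, sex: female, bound: 110.0}
  - id: L7
    category: laboratory
    description: "Blood sodium > 145 mmol/L"
    condition:
      shape: threshold
      analyte: sodium
      comparator: ">"
      bound: 145.0
  - id: A1
    category: antidote
    description: "Use of vasopressors (norepinephrine, dobutamine, mesalamine, ephedrine)"
    condition: {shape: exposure, drug_class: A1_vasopressors}
  - id: A2
    category: antidote
    description: "Use of antiemetics (metoclopramide, ondansetron, ...)"
    condition: {shape: exposure, drug_class: A2_antiemetics}
  - id: A3
    category: antidote
    description: "Use of antidiarrheals (montmorillonite, loperamide, probiotics, ...)"
    condition: {shape: exposure, drug_class: A3_antidiarrheals}
  - id: A4
    category: antidote
    description: "Use of hepatoprotectives (glutathione, glycyrrhizinates, ...)"
    condition: {shape: exposure, drug_class: A4_hepatoprotectives}
  - id: A5
    category: antidote
    description: "Use of laxatives or stool-softeners (lactulose, senna, ...)"
    condition: {shape: exposure, drug_class: A5_laxatives}
  - id: A6
    category: antidote
    description: "Use of antihistamines (loratadine, cetirizine, ...)"
    condition: {shape: exposure, drug_class: A6_antihistamines}
  - id: S1
    category: symptom
    description: "Bleeding (rectal, nose, eye, intra-abdominal, GI, subcutaneous, urinary, ...)"
    condition: {shape: symptom, group: S1}
  - id: S2
    category: symptom
    description: "Nausea, vomiting, abdominal pain, diarrhea, bloating"
    condition: {shape: symptom, group: S2}
  - id: S3
    category: symptom
    description: "Arthralgia or bone/jaw/back/neck/chest pain"
    condition: {shape: symptom, group: S3}
  - id: S4
    category: symptom
    description: "Flushing, rash, itching, hives, eczema"
    condition: {shape: symptom, group: S4}
  - id: S5
    category: symptom
    description: "Peripheral edema, puffiness, edema, swelling"
    condition: {shape: symptom, group: S5}
  - id: S6
    category: symptom
    description: "Dizziness, headaches"
    condition: {shape: symptom, group: S6}
  - id: S7
    category: symptom
    description: "Neuropsychiatric events (insomnia, anxiety, fainting, neuralgia, ...)"
    condition: {shape: symptom, group: S7}
  - id: S8
    category: symptom
    description: "Renal injury (AKI, oliguria, anuria, proteinuria, hematuria, ...)"
    condition: {shape: symptom, group: S8}
  - id: T1
    category: treatment
    description: "Transfer to ICU"
    condition: {shape: intervention, kind: icu_transfer}
  - id: T2
    category: treatment
    description: "Salvage"
    condition: {shape: intervention, kind: salvage}
  - id: T3
    category: treatment
    description: "Abrupt cessation of a targeted medication"
    condition: {shape: abrupt_cessation}
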