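# Controlled symptom vocabulary for clinical-event triggers S1-S8.
# `terms` maps canonical term codes to the symptom-trigger group they belong to;
# `aliases` maps free-text variants to canonical codes (matched after lowercasing
# and whitespace normalization). Users may extend both sections.
terms:
  # S1 bleeding
  rectal_bleeding: S1
  nosebleed: S1
  eye_bleeding: S1
  intra_abdominal_bleeding: S1
  hemorrhage: S1
  bleeding_tendency: S1
  severe_bleeding: S1
  vomiting_blood: S1
  gastrointestinal_bleeding: S1
  subcutaneous_bleeding: S1
  urinary_tract_bleeding: S1
  # S2 gastrointestinal
  nausea: S2
  vomiting: S2
  abdominal_pain: S2
  diarrhea: S2
  bloating: S2
  # S3 musculoskeletal pain
  arthralgia: S3
  bone_pain: S3
  jaw_pain: S3
  back_pain: S3
  neck_pain: S3
  chest_pain: S3
  # S4 skin / flushing
  flushing: S4
  hot_flushes: S4
  rash: S4
  itching: S4
  hives: S4
  eczema: S4
  # S5 edema
  peripheral_edema: S5
  edema: S5
  swelling: S5
  angioedema: S5
  lower_extremity_edema: S5
  fluid_retention: S5
  retinal_edema: S5
  facial_edema: S5
  # S6 dizziness / headache
  dizziness: S6
  headache: S6
  # S7 neuropsychiatric
  insomnia: S7
  anxiety: S7
  transient_amnesia: S7
  depression: S7
  drowsiness: S7
  vertigo: S7
  upright_vertigo: S7
  fainting: S7
  loss_of_consciousness: S7
  numbness: S7
  floating_sensation: S7
  neuralgia: S7
  neuropathy: S7
  # S8 renal
  kidney_injury: S8
  acute_kidney_injury: S8
  oliguria: S8
  anuria: S8
  acute_tubular_necrosis: S8
  tubular_dysfunction: S8
  proteinuria: S8
  hematuria: S8
  chronic_kidney_damage: S8
aliases:
  "joint pain": arthralgia
  "puffiness": edema
  "facial flushing": flushing
  "hot flush": hot_flushes
  "urticaria": hives
  "pruritus": itching
  "headaches": headache
  "nosebleeds": nosebleed
  "epistaxis": nosebleed
  "unconsciousness": loss_of_consciousness
  "disorientation": loss_of_consciousness
  "syncope": fainting
  "lower limb edema": lower_extremity_edema
  "haematuria": hematuria
  "stomach ache": abdominal_pain
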