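# Drug-class dictionary for antidote-trigger resolution and target-drug tagging.
# Class ids A1-A6 are the antidote trigger classes; pah_* are the eight targeted
# PAH drug classes. Lookup is case- and whitespace-insensitive; unknown names
# resolve to "other".
classes:
  A1_vasopressors:
    - norepinephrine
    - dobutamine
    - mesalamine
    - ephedrine
    - dopamine
    - phenylephrine
  A2_antiemetics:
    - metoclopramide
    - tropisetron
    - dolasetron
    - palonosetron
    - ondansetron
    - fosaprepitant
    - aprepitant
    - phenformin
  A3_antidiarrheals:
    - montmorillonite powder
    - bifidobacterium bifidum tetragonum
    - live combined bifidobacterium and lactobacillus tablets
    - bifidobacterium live bacteria
    - loperamide
    - saccharomyces boulardii
    - live bacillus cereus bifidus
  A4_hepatoprotectives:
    - glutathione
    - diammonium glycyrrhizinate
    - magnesium isoglycyrrhizinate
    - complex glycyrrhizin
    - monoammonium cysteine glycyrrhizinate
    - polyenylphosphatidylcholine
    - ursodeoxycholic acid
    - silymarin
  A5_laxatives:
    - glycerine enema
    - lactulose oral solution
    - lactulose
    - hemp nut soft gels
    - bisacodyl enteric tablets
    - bisacodyl
    - senna
  A6_antihistamines:
    - loratadine
    - ebastine
    - chlorpheniramine maleate
    - olopatadine
    - cetirizine
    - cyproheptadine
    - promethazine
    - diphenhydramine
  # The eight targeted PAH drugs each form their own class: the cohort's
  # "number of targeted drug classes combined" runs 1-6 of these eight.
  pah_sildenafil: [sildenafil]
  pah_tadalafil: [tadalafil]
  pah_ambrisentan: [ambrisentan]
  pah_macitentan: [macitentan]
  pah_riociguat: [riociguat]
  pah_selexipag: [selexipag]
  pah_beraprost: [beraprost]
  pah_treprostinil: [treprostinil]
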