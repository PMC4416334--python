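# Default child (1-59 months) EAVA rule set.
#
# RECONSTRUCTED criteria (see neonate_rules.yaml header note).  Main-text
# anchors encoded here: child meningitis requires stiff neck or bulging
# fontanelle; probable pneumonia requires minimum durations of fast/difficult
# breathing while possible pneumonia does not; possible malaria is fever with
# no other infectious diagnosis; the pertussis rule follows a CDC-style
# clinical case definition (prolonged cough with whoop or post-tussive
# vomiting).  Possible tiers sit below their probable counterparts and below
# the residual other-infections rule, claiming deaths that would otherwise be
# unspecified.
ruleset_id: niger-vasa-child-reconstruction
version: "1.0"
age_group: child

vocabulary:
  - injury_event
  - visible_wasting
  - swollen_feet
  - oral_thrush
  - swollen_glands
  - rash
  - red_eyes
  - runny_nose
  - stiff_neck
  - bulging_fontanelle
  - convulsions
  - lethargy
  - unconscious
  - fever
  - chills
  - pallor
  - loose_stools
  - frequent_stools
  - blood_in_stool
  - cough
  - whooping_cough
  - vomit_after_cough
  - fast_breathing
  - difficult_breathing
  - chest_indrawing
  - grunting
  - bleeding_anywhere
  - ear_discharge
  - skin_pustules
  - abdominal_swelling

maternal_vocabulary: []

# Injury on top (external cause), then AIDS and underlying malnutrition (both
# immune-impairing, hence ranked as underlying causes), measles above
# pneumonia and diarrhea above pneumonia (consequence rules), meningitis high
# as the severe site-specific diagnosis.
hierarchy:
  - {cause: injury, comorbid: false}
  - {cause: aids, comorbid: true}
  - {cause: malnutrition, comorbid: true}
  - {cause: measles, comorbid: true}
  - {cause: meningitis, comorbid: true}
  - {cause: dysentery, comorbid: true}
  - {cause: diarrhea, comorbid: true}
  - {cause: pertussis, comorbid: true}
  - {cause: pneumonia, comorbid: true}
  - {cause: malaria, comorbid: true}
  - {cause: hemorrhagic_fever, comorbid: true}
  - {cause: other_infections, comorbid: true}
  - {cause: possible_dysentery, comorbid: true}
  - {cause: possible_diarrhea, comorbid: true}
  - {cause: possible_pneumonia, comorbid: true}
  - {cause: possible_malaria, comorbid: true}

rules:
  - cause: injury
    expr:
      all:
        - {sign: injury_event}

  - cause: aids
    expr:
      all:
        - any:
            - {sign: loose_stools, min_duration: 30}
            - {sign: fever, min_duration: 30}
        - any:
            - {sign: oral_thrush}
            - {sign: swollen_glands}
            - {sign: visible_wasting}

  - cause: malnutrition
    expr:
      any:
        - {sign: visible_wasting}
        - {sign: swollen_feet}

  - cause: measles
    expr:
      all:
        - {sign: rash}
        - {sign: fever}
        - any:
            - {sign: red_eyes}
            - {sign: runny_nose}
            - {sign: cough}

  - cause: meningitis
    expr:
      all:
        - any:
            - {sign: stiff_neck}
            - {sign: bulging_fontanelle}
        - {sign: fever}
        - any:
            - {sign: convulsions}
            - {sign: lethargy}
            - {sign: unconscious}

  - cause: dysentery
    expr:
      all:
        - {sign: loose_stools}
        - {sign: blood_in_stool}

  - cause: diarrhea
    expr:
      all:
        - {sign: loose_stools}
        - {sign: frequent_stools}

  - cause: pertussis
    expr:
      all:
        - {sign: cough, min_duration: 14}
        - any:
            - {sign: whooping_cough}
            - {sign: vomit_after_cough}

  - cause: pneumonia
    expr:
      all:
        - {sign: cough}
        - any:
            - {sign: fast_breathing, min_duration: 2}
            - {sign: difficult_breathing, min_duration: 2}
        - any:
            - {sign: chest_indrawing}
            - {sign: grunting}

  - cause: malaria
    expr:
      all:
        - {sign: fever}
        - any:
            - {sign: chills}
            - {sign: pallor}
        - not: {sign: rash}

  - cause: hemorrhagic_fever
    expr:
      all:
        - {sign: fever}
        - {sign: bleeding_anywhere}

  - cause: other_infections
    expr:
      all:
        - {sign: fever}
        - any:
            - {sign: ear_discharge}
            - {sign: skin_pustules}
            - {sign: abdominal_swelling}

  # Sensitive tiers: fire only when the probable counterpart does not.
  - cause: possible_dysentery
    tier: possible
    counterpart: dysentery
    expr:
      all:
        - {sign: blood_in_stool}

  - cause: possible_diarrhea
    tier: possible
    counterpart: diarrhea
    expr:
      all:
        - {sign: loose_stools}

  - cause: possible_pneumonia
    tier: possible
    counterpart: pneumonia
    expr:
      any:
        - {sign: cough}
        - {sign: fast_breathing}
        - {sign: difficult_breathing}

  # Fever with no other infectious diagnosis.
  - cause: possible_malaria
    tier: possible
    counterpart: malaria
    expr:
      all:
        - {sign: fever}
        - not:
            any:
              - {sign: rash}
              - {sign: loose_stools}
              - {sign: blood_in_stool}
              - {sign: stiff_neck}
              - {sign: bulging_fontanelle}
              - {sign: cough}
              - {sign: fast_breathing}
              - {sign: difficult_breathing}
              - {sign: bleeding_anywhere}
              - {sign: ear_discharge}
              - {sign: skin_pustules}

minimum_criteria:
  pneumonia:
    any:
      - {sign: difficult_breathing}
      - {sign: fast_breathing}
  meningitis:
    any:
      - {sign: convulsions}
      - {sign: stiff_neck}
      - {sign: bulging_fontanelle}
  malaria:
    any:
      - {sign: fever}
  measles:
    any:
      - {sign: rash}
  diarrhea:
    any:
      - {sign: loose_stools}
  dysentery:
    any:
      - {sign: blood_in_stool}
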