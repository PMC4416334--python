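# Default neonatal (0-27 days) EAVA rule set.
#
# The concrete sign/symptom criteria are RECONSTRUCTIONS: they encode every
# criterion stated in the study's main text (meningitis requiring bulging
# fontanelle or convulsions PLUS lethargy or unconsciousness; preterm delivery
# as pregnancy <8 months, or <9 months with respiratory-distress signs;
# minimum sign durations for pneumonia) and fill the remaining causes from the
# verbal-autopsy validation literature.  Edit freely; the engine validates the
# schema at load and records ruleset_id/version in all outputs.
ruleset_id: niger-vasa-neonate-reconstruction
version: "1.0"
age_group: neonate

vocabulary:
  - suckled_normally_first_days
  - stopped_suckling
  - spasms
  - convulsions
  - arched_back
  - visible_malformation
  - not_cried_at_birth
  - not_breathed_at_birth
  - resuscitated
  - bruises_or_birth_injury
  - bulging_fontanelle
  - lethargy
  - unconscious
  - fever
  - hypothermia
  - loose_stools
  - frequent_stools
  - fast_breathing
  - difficult_breathing
  - chest_indrawing
  - grunting
  - vomit_everything
  - yellow_skin
  - yellow_palms_eyes
  - bleeding_anywhere
  - appeared_healthy_then_died_suddenly

maternal_vocabulary:
  - fever_during_labor
  - foul_smelling_discharge

# Total order, rank 1 first; unspecified is implicit at the bottom.
# Preterm delivery is deliberately last so that it is primary only when it is
# the sole condition found (ICD-10 perinatal rule); meningitis sits above
# sepsis to keep the site-specific, more severe diagnosis on top.
hierarchy:
  - {cause: neonatal_tetanus, comorbid: false}
  - {cause: congenital_malformation, comorbid: false}
  - {cause: birth_injury_asphyxia, comorbid: true}
  - {cause: meningitis, comorbid: true}
  - {cause: diarrhea, comorbid: true}
  - {cause: pneumonia, comorbid: true}
  - {cause: sepsis, comorbid: true}
  - {cause: neonatal_jaundice, comorbid: false}
  - {cause: hemorrhagic_disease, comorbid: true}
  - {cause: sudden_unexplained_death, comorbid: false}
  - {cause: preterm_delivery, comorbid: true}

rules:
  - cause: neonatal_tetanus
    expr:
      all:
        - {sign: suckled_normally_first_days}
        - {sign: stopped_suckling}
        - any:
            - {sign: convulsions}
            - {sign: spasms}
            - {sign: arched_back}

  - cause: congenital_malformation
    expr:
      all:
        - {sign: visible_malformation}

  - cause: birth_injury_asphyxia
    expr:
      any:
        - {sign: bruises_or_birth_injury}
        - {sign: not_cried_at_birth}
        - {sign: not_breathed_at_birth}
        - {sign: resuscitated}

  - cause: meningitis
    expr:
      all:
        - any:
            - {sign: bulging_fontanelle}
            - {sign: convulsions}
        - any:
            - {sign: lethargy}
            - {sign: unconscious}

  - cause: diarrhea
    expr:
      all:
        - {sign: loose_stools}
        - {sign: frequent_stools}

  - cause: pneumonia
    expr:
      all:
        - any:
            - {sign: fast_breathing, min_duration: 2}
            - {sign: difficult_breathing, min_duration: 2}
        - any:
            - {sign: chest_indrawing}
            - {sign: grunting}

  - cause: sepsis
    expr:
      all:
        - any:
            - {sign: fever}
            - {sign: hypothermia}
        - any:
            - {sign: stopped_suckling}
            - {sign: lethargy}
            - {sign: unconscious}
            - {sign: vomit_everything}
            - {sign: convulsions}

  - cause: neonatal_jaundice
    expr:
      all:
        - {sign: yellow_skin}
        - {sign: yellow_palms_eyes}

  - cause: hemorrhagic_disease
    expr:
      all:
        - {sign: bleeding_anywhere}
        - not: {sign: fever}

  - cause: sudden_unexplained_death
    expr:
      all:
        - {sign: appeared_healthy_then_died_suddenly}

  - cause: preterm_delivery
    expr:
      any:
        - {pregnancy_months_lt: 8}
        - all:
            - {pregnancy_months_lt: 9}
            - {sign: fast_breathing}
            - {sign: chest_indrawing}

# Infection of the mother before or during labor and delivery.
maternal_rule:
  cause: maternal_infection
  expr:
    any:
      - {sign: fever_during_labor, scope: maternal}
      - {sign: foul_smelling_discharge, scope: maternal}

# Minimal diagnostic floors for auditing physician certificates.
minimum_criteria:
  meningitis:
    any:
      - {sign: bulging_fontanelle}
      - {sign: convulsions}
  pneumonia:
    any:
      - {sign: fast_breathing}
      - {sign: difficult_breathing}
  sepsis:
    any:
      - {sign: fever}
      - {sign: hypothermia}
  preterm_delivery:
    any:
      - {pregnancy_months_lt: 8}
      - all:
          - {pregnancy_months_lt: 9}
          - {sign: fast_breathing}
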