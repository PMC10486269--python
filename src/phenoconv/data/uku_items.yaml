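# Adapted UKU side-effect item list (39 items, extrapyramidal symptoms
# excluded).  cyp_related marks the 33 items used for the per-item
# phenotype prevalence comparisons.  The published tables print 30 item
# names plus three items dropped for zero prevalence (epileptic seizures,
# amenorrhea, galactorrhea); the remaining six items of the adapted scale
# are standard UKU psychic/autonomic items assessed as not CYP-related.
items:
  - {name: fatigue, cyp_related: true}
  - {name: sleepiness, cyp_related: true}
  - {name: depression, cyp_related: true}
  - {name: tension_inner_unrest, cyp_related: true}
  - {name: increased_duration_of_sleep, cyp_related: true}
  - {name: reduced_duration_of_sleep, cyp_related: true}
  - {name: increased_dream_activity, cyp_related: true}
  - {name: paresthesia, cyp_related: true}
  - {name: increased_salivation, cyp_related: true}
  - {name: dry_mouth, cyp_related: true}
  - {name: nausea_vomiting, cyp_related: true}
  - {name: diarrhea, cyp_related: true}
  - {name: constipation, cyp_related: true}
  - {name: micturition_disturbances, cyp_related: true}
  - {name: orthostatic_dizziness, cyp_related: true}
  - {name: palpitations_tachycardia, cyp_related: true}
  - {name: increased_tendency_to_sweating, cyp_related: true}
  - {name: rash, cyp_related: true}
  - {name: pruritus, cyp_related: true}
  - {name: weight_gain, cyp_related: true}
  - {name: weight_loss, cyp_related: true}
  - {name: menorrhagia, cyp_related: true}
  - {name: gynecomastia, cyp_related: true}
  - {name: increased_sexual_desire, cyp_related: true}
  - {name: diminished_sexual_desire, cyp_related: true}
  - {name: erectile_dysfunction, cyp_related: true}
  - {name: ejaculatory_dysfunction, cyp_related: true}
  - {name: orgasmic_dysfunction, cyp_related: true}
  - {name: dry_vagina, cyp_related: true}
  - {name: headache, cyp_related: true}
  - {name: epileptic_seizures, cyp_related: true}
  - {name: amenorrhea, cyp_related: true}
  - {name: galactorrhea, cyp_related: true}
  - {name: concentration_difficulties, cyp_related: false}
  - {name: failing_memory, cyp_related: false}
  - {name: emotional_indifference, cyp_related: false}
  - {name: accommodation_disturbances, cyp_related: false}
  - {name: reduced_salivation, cyp_related: false}
  - {name: polyuria_polydipsia, cyp_related: false}
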