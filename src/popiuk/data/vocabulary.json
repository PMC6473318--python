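{
 "conditions": [
  "pain",
  "fever",
  "migraine",
  "urinary_tract_infection",
  "asymptomatic_bacteriuria",
  "sickle_cell_anaemia",
  "vomiting",
  "gord_regurgitation",
  "dehydration",
  "diarrhoea",
  "diarrhoea_invasive",
  "cough",
  "bronchiolitis",
  "chronic_lung_disease",
  "congenital_heart_disease",
  "immunodeficiency",
  "upper_respiratory_tract_infection",
  "acute_otitis_media",
  "otitis_media_with_effusion",
  "sore_throat",
  "nasopharyngitis",
  "strep_throat",
  "asthma",
  "persistent_asthma",
  "allergic_rhinitis",
  "acne_vulgaris",
  "scabies",
  "head_lice",
  "ringworm_microsporum",
  "impetigo",
  "herpes_simplex",
  "herpetic_gingivostomatitis",
  "atopic_eczema",
  "epilepsy_myoclonic",
  "epilepsy_absence",
  "depression",
  "nocturnal_enuresis",
  "anorexia_nervosa",
  "adhd",
  "anaphylaxis",
  "chemotherapy"
 ],
 "qualifiers": [
  "severe",
  "clinical_concern_documented",
  "bilateral",
  "otorrhoea",
  "centor_ge_3",
  "feeding_difficulties",
  "distress",
  "faltering_growth",
  "daytime_symptoms",
  "sleep_disturbance_significant",
  "severe_itching",
  "shock",
  "red_flags_despite_ors",
  "persistent_vomiting_of_ors",
  "iv_fluids_indicated",
  "home_oxygen",
  "prolonged_oxygen_use",
  "haemodynamically_significant",
  "pulmonary_hypertension",
  "severe_congenital",
  "hearing_loss",
  "lichenification_severe",
  "penicillin_allergic",
  "uropathy",
  "gi_risk_factors",
  "fusidic_acid_allergy",
  "menstruating"
 ]
}
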