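{
  "patients": {
    "patient_id": {"type": "string", "required": true},
    "diagnosis_group": {"type": "enum", "values": ["CNS", "SOLID", "HM"], "required": true},
    "enrollment_day": {"type": "int", "required": true},
    "enrollment_status": {"type": "enum", "values": ["DIAGNOSIS", "FIRST_RELAPSE", "GE2_RELAPSE"], "required": true},
    "mtb_day": {"type": "int", "required": true},
    "death_day": {"type": "int", "required": false},
    "last_followup_day": {"type": "int", "required": true},
    "progression_days": {"type": "int_list", "required": false, "note": "semicolon-separated, strictly increasing"}
  },
  "recommendations": {
    "recommendation_id": {"type": "string", "required": true},
    "patient_id": {"type": "string", "required": true},
    "tier": {"type": "enum", "values": ["T1", "T2", "T3", "T4", "T5"], "required": true},
    "target_gene": {"type": "string", "required": true},
    "aberration_class": {"type": "enum", "values": ["FUSION_SV", "SNV", "CNV", "HIGH_RNA_ONLY", "OTHER"], "required": true},
    "therapy_type": {"type": "enum", "values": ["TARGETED_MONO", "TARGETED_DUAL", "TARGETED_PLUS_CHEMO", "CHEMO"], "required": true}
  },
  "courses": {
    "course_id": {"type": "string", "required": true},
    "patient_id": {"type": "string", "required": true},
    "category": {"type": "enum", "values": ["PGT", "UGT", "SOC", "OTHER"], "required": true},
    "recommendation_id": {"type": "string", "required": false, "note": "required when category is PGT"},
    "start_day": {"type": "int", "required": true},
    "stop_day": {"type": "int", "required": true},
    "baseline_state": {"type": "enum", "values": ["MEASURABLE", "NONMEASURABLE_EVALUABLE", "NED"], "required": true},
    "n_progressions_before_start": {"type": "int", "required": true},
    "modality": {"type": "enum", "values": ["RECIST", "RANO", "PERCIST", "LEUKEMIA"], "required": true},
    "pre_mtb": {"type": "bool", "required": false}
  },
  "assessments": {
    "course_id": {"type": "string", "required": true},
    "day": {"type": "int", "required": true},
    "target_sum": {"type": "float", "required": false},
    "nonmeasurable_status": {"type": "enum", "values": ["DISAPPEARED", "PERSISTS", "UNEQUIVOCAL_PROGRESSION"], "required": false},
    "new_lesions": {"type": "bool", "required": false},
    "marrow_blast_pct": {"type": "float", "required": false},
    "circulating_blast_abs": {"type": "float", "required": false},
    "extramedullary": {"type": "bool", "required": false}
  }
}
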