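{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Arm-level VAP incidence record",
  "description": "Columns of the CSV exchange format for component patient groups. One row per study arm; missing optional values are empty cells.",
  "type": "object",
  "properties": {
    "study_id": {"type": "string", "description": "Identifier of the originating study; arms of multi-arm studies share it."},
    "group_label": {"type": "string", "description": "Free-text label shown in plots; defaults to study_id."},
    "arm_role": {"enum": ["benchmark", "control", "intervention"]},
    "series": {"enum": ["benchmark", "sdd", "non_antimicrobial"]},
    "events": {"type": "integer", "minimum": 0, "description": "VAP cases observed in the group (N)."},
    "denominator": {"type": "integer", "minimum": 1, "description": "Patients in the group (D); events <= denominator."},
    "bronchoscopic_diagnosis": {"type": ["boolean", "null"], "description": "True when VAP diagnosis required bronchoscopic sampling."},
    "trauma_proportion": {"type": ["number", "null"], "minimum": 0, "maximum": 1, "description": "Proportion of ICU admissions for trauma, as a fraction."},
    "mv_lt90": {"type": ["boolean", "null"], "description": "True when <90% of the group received >24 h of mechanical ventilation."},
    "quality_majority": {"type": ["boolean", "null"], "description": "True when the study received a majority quality score in its source systematic review."},
    "duplex": {"type": "boolean", "description": "True when all control-group patients routinely received systemic antibiotics."},
    "concurrent": {"type": "boolean", "description": "True when control and intervention groups were treated concurrently in the same ICU."},
    "european": {"type": ["boolean", "null"]},
    "publication_year": {"type": ["integer", "null"]},
    "source_review": {"type": "string", "description": "Identifier of the review the data were abstracted from."}
  },
  "required": ["study_id", "arm_role", "series", "events", "denominator"]
}
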