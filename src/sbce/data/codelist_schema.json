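{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SBCE code-list file",
  "description": "Schema for the YAML code-list files consumed by sbce.codelists.load_codelists. One section per criterion, one sub-block per data source.",
  "type": "object",
  "required": ["criteria"],
  "properties": {
    "provenance": {"type": "string"},
    "criteria": {
      "type": "object",
      "required": [
        "death_breast_cancer",
        "procedure_diagnosis",
        "systemic_treatment",
        "radiotherapy"
      ],
      "additionalProperties": false,
      "properties": {
        "death_breast_cancer": {"$ref": "#/$defs/criterionSection"},
        "procedure_diagnosis": {"$ref": "#/$defs/criterionSection"},
        "systemic_treatment": {"$ref": "#/$defs/criterionSection"},
        "radiotherapy": {"$ref": "#/$defs/criterionSection"}
      }
    }
  },
  "$defs": {
    "codeSet": {
      "type": "object",
      "required": ["code_system", "codes"],
      "properties": {
        "code_system": {"type": "string"},
        "match_mode": {"enum": ["exact", "prefix"]},
        "codes": {
          "type": "array",
          "minItems": 1,
          "items": {"type": ["string", "number"]}
        }
      }
    },
    "criterionSection": {
      "type": "object",
      "minProperties": 1,
      "additionalProperties": {
        "allOf": [
          {"$ref": "#/$defs/codeSet"},
          {
            "type": "object",
            "properties": {"diagnosis": {"$ref": "#/$defs/codeSet"}}
          }
        ]
      }
    }
  }
}
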