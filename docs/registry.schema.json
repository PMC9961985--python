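{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "scoredrift reference registry",
  "type": "object",
  "required": ["entries"],
  "properties": {
    "entries": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["ai_version", "modality", "manufacturer", "n_exams", "bins"],
        "properties": {
          "ai_version": {
            "type": "string",
            "pattern": "^\\d+\\.\\d+([.\\-].*)?$",
            "description": "Dotted AI version; matching uses major.minor"
          },
          "modality": {"enum": ["FFDM", "DBT"]},
          "manufacturer": {"type": "string", "minLength": 1},
          "n_exams": {"type": "integer", "exclusiveMinimum": 0},
          "bins": {
            "type": "array",
            "minItems": 10,
            "maxItems": 10,
            "items": {"type": "integer", "minimum": 0},
            "description": "Counts for scores 1..10; must sum to n_exams"
          },
          "provenance": {"type": "string"}
        }
      }
    }
  }
}
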