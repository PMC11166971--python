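{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "kiddi annotated dialogue corpus",
  "type": "object",
  "required": ["dialogues"],
  "properties": {
    "dialogues": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "disease", "turns"],
        "properties": {
          "id": {"type": "string"},
          "disease": {"type": "string"},
          "turns": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["speaker", "text", "symptoms"],
              "properties": {
                "speaker": {"enum": ["patient", "doctor"]},
                "text": {"type": "string"},
                "intent": {"enum": ["Symptom", "Affirmative"]},
                "symptoms": {"type": "array", "items": {"type": "string"}}
              },
              "additionalProperties": false
            }
          }
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
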