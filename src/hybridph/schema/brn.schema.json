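{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "BRN-JSON: interaction graph of a biological regulatory network",
  "type": "object",
  "required": ["genes", "interactions"],
  "properties": {
    "genes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "max_level"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "max_level": {"type": "integer", "minimum": 1},
          "input": {"enum": ["rise", "fall", "both"]}
        },
        "additionalProperties": false
      }
    },
    "interactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "threshold", "sign"],
        "properties": {
          "source": {"type": "string"},
          "target": {"type": "string"},
          "threshold": {"type": "integer", "minimum": 1},
          "sign": {"enum": ["+", "-"]}
        },
        "additionalProperties": false
      }
    },
    "logic": {
      "type": "object",
      "additionalProperties": {
        "type": "string",
        "description": "boolean formula over regulator names: atoms, !, &, |, parentheses"
      }
    }
  },
  "additionalProperties": false
}
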