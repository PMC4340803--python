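{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://medmod.dev/schemas/model.schema.json",
  "title": "MedMod process model",
  "type": "object",
  "required": ["name"],
  "properties": {
    "name": {"type": "string"},
    "enumerations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "literals"],
        "properties": {
          "name": {"type": "string"},
          "literals": {"type": "array", "items": {"type": "string"}, "minItems": 1}
        }
      }
    },
    "activities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "is_master": {"type": "boolean", "default": false},
          "attributes": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["name", "type"],
              "properties": {
                "name": {"type": "string"},
                "type": {
                  "type": "string",
                  "description": "Integer, Real, String, Boolean, DateTime, or the name of an enumeration declared in this model"
                }
              }
            }
          }
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "source", "target"],
        "properties": {
          "kind": {"enum": ["follows", "composition", "interruption", "extension"]},
          "source": {"type": "string"},
          "target": {"type": "string"},
          "cardinality": {
            "enum": ["1", "0..1", "1..*", "*"],
            "description": "composition edges only; default 1"
          },
          "extension_point": {
            "type": "string",
            "description": "extension edges only; the guard condition's name"
          }
        }
      }
    }
  }
}
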