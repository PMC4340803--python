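{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://medmod.dev/schemas/query.schema.json",
  "title": "PQL query",
  "type": "object",
  "properties": {
    "conditions": {
      "type": "array",
      "description": "ordered filtering conditions; each keeps whole slices",
      "items": {
        "oneOf": [
          {
            "type": "object",
            "required": ["type", "activity", "attribute", "op", "value"],
            "properties": {
              "type": {"const": "comparison"},
              "activity": {"type": "string"},
              "attribute": {
                "type": "string",
                "description": "declared attribute, the reserved target 'count', or a defined interval name"
              },
              "op": {"enum": ["eq", "ne", "gt", "lt", "ge", "le", "contains", "begins_with", "ends_with"]},
              "value": {},
              "combine": {"enum": ["and", "or"]},
              "op2": {"enum": ["eq", "ne", "gt", "lt", "ge", "le", "contains", "begins_with", "ends_with"]},
              "value2": {}
            }
          },
          {
            "type": "object",
            "required": ["type", "activity", "function", "op", "value"],
            "properties": {
              "type": {"const": "aggregate"},
              "activity": {"type": "string"},
              "function": {"enum": ["sum", "average", "count"]},
              "attribute": {"type": "string", "description": "numeric attribute; absent for count"},
              "op": {"enum": ["eq", "ne", "gt", "lt", "ge", "le"]},
              "value": {"type": "number"}
            }
          }
        ]
      }
    },
    "partitions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["activity", "attribute", "direction", "k"],
        "properties": {
          "activity": {"type": "string"},
          "attribute": {"type": "string"},
          "direction": {"enum": ["top", "bottom"]},
          "k": {"type": "integer", "minimum": 1}
        }
      }
    },
    "intervals": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "start_activity", "end_activity"],
        "properties": {
          "name": {"type": "string"},
          "start_activity": {"type": "string"},
          "start_attribute": {"type": ["string", "null"], "description": "DateTime attribute; default the instance's intrinsic start"},
          "end_activity": {"type": "string"},
          "end_attribute": {"type": ["string", "null"]},
          "pairing": {
            "type": ["object", "null"],
            "description": "pair only start/end instances whose attributes are equal",
            "properties": {
              "start_attribute": {"type": "string"},
              "end_attribute": {"type": "string"}
            }
          }
        }
      }
    },
    "grouping": {
      "type": ["object", "null"],
      "required": ["activity", "attribute"],
      "properties": {
        "activity": {"type": "string"},
        "attribute": {"type": "string"}
      }
    },
    "retrievals": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "activity"],
        "properties": {
          "kind": {"enum": ["count", "sum", "average", "table"]},
          "activity": {"type": "string"},
          "attribute": {"type": "string"}
        }
      }
    }
  }
}
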