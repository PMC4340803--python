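{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://medmod.dev/schemas/simulation_config.schema.json",
  "title": "Simulation configuration",
  "description": "Sampling tables for the trace generator. A distribution spec is one of {\"constant\": v}, {\"uniform\": [lo, hi]}, {\"exponential\": mean}, {\"categorical\": {value: weight, ...}}. Durations and gaps are seconds. Edge-keyed tables use 'source -> target' keys in the serialized form.",
  "type": "object",
  "required": ["n_slices", "seed", "time_origin", "inter_arrival"],
  "properties": {
    "n_slices": {"type": "integer", "minimum": 0},
    "seed": {"type": "integer"},
    "time_origin": {"type": "string", "format": "date-time"},
    "inter_arrival": {"$ref": "#/$defs/distribution"},
    "branch_weights": {
      "type": "object",
      "description": "source activity -> {target: weight}; weights over one source's XOR follows alternatives must sum to 1",
      "additionalProperties": {"type": "object", "additionalProperties": {"type": "number"}}
    },
    "interruption_weights": {
      "type": "object",
      "additionalProperties": {"type": "object", "additionalProperties": {"type": "number"}}
    },
    "extension_probability": {"type": "object", "additionalProperties": {"type": "number"}},
    "component_counts": {
      "type": "object",
      "description": "realized component counts per composition edge; support must respect the declared cardinality",
      "additionalProperties": {"$ref": "#/$defs/distribution"}
    },
    "durations": {"type": "object", "additionalProperties": {"$ref": "#/$defs/distribution"}},
    "attribute_generators": {
      "type": "object",
      "description": "activity -> {attribute: distribution}",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {"$ref": "#/$defs/distribution"}
      }
    },
    "derived_sums": {
      "type": "array",
      "items": {"type": "array", "prefixItems": [{"type": "string"}, {"type": "string"}]}
    },
    "follow_gap": {"$ref": "#/$defs/distribution"},
    "spawn_gap": {"$ref": "#/$defs/distribution"},
    "interruption_gap": {"$ref": "#/$defs/distribution"}
  },
  "$defs": {
    "distribution": {
      "type": "object",
      "minProperties": 1,
      "maxProperties": 1,
      "properties": {
        "constant": {},
        "uniform": {"type": "array", "prefixItems": [{"type": "number"}, {"type": "number"}]},
        "exponential": {"type": "number", "exclusiveMinimum": 0},
        "categorical": {"type": "object", "additionalProperties": {"type": "number"}}
      }
    }
  }
}
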