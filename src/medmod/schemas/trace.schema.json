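{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://medmod.dev/schemas/trace.schema.json",
  "title": "Run-time trace dataset (JSON dialect)",
  "description": "Instances grouped into transaction slices. Timestamps are ISO-8601 with timezone; attribute values are typed per the model; the CSV dialect carries the same information flat, one column per declared attribute.",
  "type": "object",
  "required": ["slices"],
  "properties": {
    "model": {"type": "string", "description": "name of the process model this trace conforms to"},
    "slices": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["slice_id", "instances"],
        "properties": {
          "slice_id": {"type": "string"},
          "instances": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["instance_id", "activity", "start_time"],
              "properties": {
                "instance_id": {"type": "string"},
                "activity": {"type": "string"},
                "start_time": {"type": "string", "format": "date-time"},
                "end_time": {"type": ["string", "null"], "format": "date-time"},
                "attributes": {"type": "object"},
                "caused_by": {
                  "type": ["object", "null"],
                  "required": ["predecessor", "kind"],
                  "properties": {
                    "predecessor": {"type": "string"},
                    "kind": {"enum": ["follows", "composition", "interruption", "extension"]}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
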