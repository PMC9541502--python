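{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "batchsw power result",
  "type": "object",
  "required": ["var_per_batch", "var_combined", "power", "manifest"],
  "properties": {
    "var_per_batch": {
      "type": "array",
      "minItems": 1,
      "items": {"type": "number", "exclusiveMinimum": 0}
    },
    "var_combined": {"type": "number", "exclusiveMinimum": 0},
    "power": {"type": "number", "minimum": 0, "maximum": 1},
    "manifest": {
      "type": "object",
      "required": ["command", "config_hash", "version", "outputs"],
      "properties": {
        "command": {"type": "string"},
        "config_hash": {"type": "string"},
        "seed": {"type": ["integer", "null"]},
        "version": {"type": "string"},
        "outputs": {"type": "array", "items": {"type": "string"}}
      }
    }
  }
}
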