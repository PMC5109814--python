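{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dynlogic component record, schema version 1",
  "type": "object",
  "required": ["id", "family", "parameters", "r", "vagueness"],
  "properties": {
    "id": {"type": "integer", "minimum": 0},
    "family": {"enum": ["clutter", "blob", "parabola", "bernoulli"]},
    "parameters": {
      "type": "object",
      "description": "family-specific: blob {mean, cov}; parabola {vertex, curvature, rotation, half_extent, sigma}; bernoulli {p}; clutter {}"
    },
    "r": {"type": "number", "minimum": 0, "maximum": 1},
    "vagueness": {"type": "number", "minimum": 0}
  }
}
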