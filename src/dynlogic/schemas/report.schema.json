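{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dynlogic run report, schema version 1",
  "type": "object",
  "required": [
    "schema_version", "convergence_reason", "seed", "config",
    "components", "trace", "events", "family_counts", "final_ll"
  ],
  "properties": {
    "schema_version": {"const": "1"},
    "timestamp": {"type": "string"},
    "convergence_reason": {
      "enum": ["similarity_stopped_increasing", "max_iterations", "diverged"]
    },
    "scene_fixture": {"type": "string"},
    "seed": {"type": "integer"},
    "n_observations": {"type": "integer"},
    "total_weight": {"type": "number"},
    "n_iterations": {"type": "integer"},
    "final_ll": {"type": "number"},
    "family_counts": {"type": "object"},
    "config": {"type": "object"},
    "components": {
      "type": "array",
      "items": {"$ref": "component.schema.json"}
    },
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["iteration", "kind", "component_id", "accepted"],
        "properties": {
          "iteration": {"type": "integer"},
          "kind": {"enum": ["split", "split_parabola", "convert", "remove", "add", "merge"]},
          "component_id": {"type": "integer"},
          "accepted": {"type": "boolean"},
          "delta_penalized_ll": {"type": "number"}
        }
      }
    },
    "trace": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["t", "ll", "d_ki", "M"],
        "properties": {
          "t": {"type": "integer"},
          "ll": {"type": "number"},
          "d_ki": {"type": "number"},
          "M": {"type": "integer"}
        }
      }
    }
  }
}
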