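{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "particell simulation state document",
  "type": "object",
  "required": [
    "schema_version",
    "universe",
    "rng",
    "types",
    "particles",
    "clusters",
    "bonds",
    "angles",
    "dihedrals",
    "bindings",
    "flux_rules",
    "reactions",
    "events"
  ],
  "properties": {
    "schema_version": {"type": "integer", "const": 1},
    "universe": {
      "type": "object",
      "required": ["dims", "boundary", "cutoff", "dt", "time", "step_count", "seed"],
      "properties": {
        "dims": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
        "boundary": {"type": "array", "items": {"enum": ["periodic", "reflective"]}},
        "cutoff": {"type": "number", "exclusiveMinimum": 0},
        "dt": {"type": "number", "exclusiveMinimum": 0},
        "time": {"type": "number", "minimum": 0},
        "step_count": {"type": "integer", "minimum": 0},
        "seed": {"type": "integer"}
      }
    },
    "rng": {"type": "object"},
    "types": {"type": "array", "items": {"type": "object", "required": ["name", "mass", "dynamics"]}},
    "particles": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "type", "position", "velocity", "state", "frozen"]
      }
    },
    "clusters": {"type": "array"},
    "bonds": {"type": "array"},
    "angles": {"type": "array"},
    "dihedrals": {"type": "array"},
    "bindings": {"type": "object"},
    "flux_rules": {"type": "array"},
    "reactions": {"type": "array"},
    "events": {"type": "array"}
  }
}
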