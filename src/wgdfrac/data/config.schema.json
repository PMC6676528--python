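{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "wgdfrac run configuration",
  "type": "object",
  "required": ["model"],
  "properties": {
    "model": {
      "type": "object",
      "required": ["M1", "events"],
      "properties": {
        "type": {"enum": ["schedule", "scenario"], "default": "schedule"},
        "M1": {"type": "integer", "minimum": 1},
        "events": {"type": "array", "items": {"$ref": "#/definitions/event"}, "minItems": 1},
        "branch_a": {"$ref": "#/definitions/branch"},
        "branch_b": {"$ref": "#/definitions/branch"}
      }
    },
    "similarity": {
      "type": "object",
      "properties": {
        "decay": {
          "type": "object",
          "properties": {
            "amplitude": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
            "rate_per_my": {"type": "number", "exclusiveMinimum": 0, "default": 0.009}
          }
        },
        "sd": {
          "type": "object",
          "properties": {
            "intercept": {"type": "number", "default": 0.075},
            "slope": {"type": "number", "default": -0.06}
          }
        }
      }
    },
    "fit": {
      "type": "object",
      "properties": {
        "bin_width": {"type": "number", "exclusiveMinimum": 0, "maximum": 0.1, "default": 0.01},
        "window": {"type": "integer", "minimum": 1, "default": 5},
        "min_prominence": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.05},
        "n_components": {
          "oneOf": [
            {"type": "null"},
            {"type": "integer", "minimum": 1},
            {"type": "array", "items": {"type": "integer", "minimum": 0}, "minItems": 2, "maxItems": 2}
          ]
        }
      }
    }
  },
  "definitions": {
    "event": {
      "type": "object",
      "required": ["kind", "time"],
      "properties": {
        "kind": {"enum": ["wgd", "speciation", "observation"]},
        "time": {"type": "number", "minimum": 0, "description": "My before present"},
        "ploidy": {"type": "integer", "minimum": 2, "default": 2},
        "u": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}},
        "u0": {"type": "number", "minimum": 0, "maximum": 1, "default": 0},
        "u2": {"type": "number", "minimum": 0, "maximum": 1},
        "u3": {"type": "number", "minimum": 0, "maximum": 1}
      }
    },
    "branch": {
      "type": "object",
      "required": ["events"],
      "properties": {
        "events": {"type": "array", "items": {"$ref": "#/definitions/event"}, "minItems": 1},
        "copy_survival": {"type": ["number", "null"], "minimum": 0, "maximum": 1}
      }
    }
  }
}
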