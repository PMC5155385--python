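{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tempdx knowledge base",
  "description": "Disease-finding knowledge base with temporal evidence model. Ages are years (birth = 0); incidence age bins are half-open [lo, hi) tiling [0, 120); onset/disappearance intervals are closed.",
  "type": "object",
  "required": ["findings", "diseases", "associations", "categories", "core_checklist"],
  "properties": {
    "findings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["finding_id", "name"],
        "properties": {
          "finding_id": {"type": "string"},
          "name": {"type": "string"},
          "kind": {"enum": ["clinical", "lab", "imaging", "acuity"]},
          "cost": {"type": "number", "minimum": 0.1},
          "bundle_id": {"type": "string"},
          "is_core": {"type": "boolean"}
        }
      }
    },
    "diseases": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["disease_id", "name", "incidence"],
        "properties": {
          "disease_id": {"type": "string"},
          "name": {"type": "string"},
          "category_ids": {"type": "array", "items": {"type": "string"}},
          "incidence": {
            "type": "object",
            "required": ["age_bins", "incidence_per_bin"],
            "properties": {
              "age_bins": {
                "type": "array",
                "items": {
                  "type": "array",
                  "items": {"type": "number", "minimum": 0, "maximum": 120},
                  "minItems": 2,
                  "maxItems": 2
                }
              },
              "incidence_per_bin": {
                "type": "array",
                "items": {"type": "number", "minimum": 0}
              },
              "gender_multiplier": {
                "type": "object",
                "additionalProperties": {"type": "number", "minimum": 0}
              }
            }
          },
          "treatability": {"type": "number", "minimum": 0, "maximum": 1},
          "severity": {"type": "number", "minimum": 0, "maximum": 1},
          "heritable": {"type": "boolean"},
          "acuity_class": {
            "enum": ["minutes", "hours", "days", "weeks", "months", "years", "unknown"]
          }
        }
      }
    },
    "associations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["disease_id", "finding_id", "frequency", "onset"],
        "properties": {
          "disease_id": {"type": "string"},
          "finding_id": {"type": "string"},
          "frequency": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
          "onset": {
            "type": "array",
            "items": {"type": "number", "minimum": 0},
            "minItems": 2,
            "maxItems": 2
          },
          "disappearance": {
            "type": "array",
            "items": {"type": "number", "minimum": 0},
            "minItems": 2,
            "maxItems": 2
          }
        }
      }
    },
    "categories": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "core_checklist": {
      "type": "array",
      "items": {"type": "string"}
    }
  }
}
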