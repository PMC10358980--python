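{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Mapping-system evaluation report",
  "type": "object",
  "required": ["schema_version", "entry", "provenance", "act", "patterns", "tolerance_sweep"],
  "additionalProperties": false,
  "properties": {
    "schema_version": {"type": "integer", "const": 1},
    "entry": {"type": "string"},
    "provenance": {
      "type": "object",
      "required": ["master_seed", "noise_seed", "cell_model", "tissue_params", "noise_levels"],
      "properties": {
        "master_seed": {"type": "integer"},
        "noise_seed": {"type": "integer"},
        "cell_model": {"type": "string"},
        "tissue_params": {"type": "object"},
        "noise_levels": {"type": "object"}
      }
    },
    "act": {
      "type": "object",
      "required": ["tol", "fC", "fS", "AcTPM", "rms", "rms_sd",
                   "n_correct", "n_spurious", "n_missed", "n_truth", "per_electrode"],
      "properties": {
        "tol": {"type": "number", "minimum": 0},
        "fC": {"type": "number", "minimum": 0, "maximum": 1},
        "fS": {"type": "number", "minimum": 0, "maximum": 1},
        "AcTPM": {"type": "number", "minimum": 0, "maximum": 100},
        "rms": {"type": ["number", "null"]},
        "rms_sd": {"type": ["number", "null"]},
        "n_correct": {"type": "integer"},
        "n_spurious": {"type": "integer"},
        "n_missed": {"type": "integer"},
        "n_truth": {"type": "integer"},
        "per_electrode": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["site", "n_truth", "n_correct", "n_spurious", "fC", "fS", "rms"],
            "properties": {
              "site": {"type": "string"},
              "n_truth": {"type": "integer"},
              "n_correct": {"type": "integer"},
              "n_spurious": {"type": "integer"},
              "fC": {"type": "number"},
              "fS": {"type": "number"},
              "rms": {"type": ["number", "null"]}
            }
          }
        }
      }
    },
    "patterns": {
      "type": "object",
      "required": ["per_type"],
      "properties": {
        "per_type": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["type", "n_truth", "n_correct", "n_misclassified",
                         "n_spurious", "fC", "fS", "fM", "AcPPM", "E_T", "E_X"],
            "properties": {
              "type": {"enum": ["P", "R+", "R-", "F+", "F-"]},
              "n_truth": {"type": "integer"},
              "n_correct": {"type": "integer"},
              "n_misclassified": {"type": "integer"},
              "n_spurious": {"type": "integer"},
              "fC": {"type": "number", "minimum": 0, "maximum": 1},
              "fS": {"type": "number", "minimum": 0, "maximum": 1},
              "fM": {"type": "number", "minimum": 0, "maximum": 1},
              "AcPPM": {"type": "number", "minimum": 0, "maximum": 100},
              "E_T": {"type": ["number", "null"]},
              "E_X": {"type": ["number", "null"]}
            }
          }
        }
      }
    },
    "tolerance_sweep": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["tol", "AcTPM", "pct_spurious", "rms", "rms_sd"],
        "properties": {
          "tol": {"type": "number"},
          "AcTPM": {"type": "number"},
          "pct_spurious": {"type": "number"},
          "rms": {"type": ["number", "null"]},
          "rms_sd": {"type": ["number", "null"]}
        }
      }
    }
  }
}
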