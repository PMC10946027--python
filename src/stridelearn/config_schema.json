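{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "stridelearn run configuration",
  "description": "YAML configuration accepted by RunConfig.from_yaml and the CLI --config flag.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "experiment": {
      "type": "string",
      "enum": ["washout", "retention"],
      "default": "washout",
      "description": "Post-learning probe: 900-stride washout (implicit aftereffects) or immediate + 24 h explicit retention tests."
    },
    "n_rpe": {"type": "integer", "minimum": 0, "default": 15},
    "n_te": {"type": "integer", "minimum": 0, "default": 15},
    "baseline_n": {"type": "integer", "minimum": 1, "default": 250},
    "learning_n": {"type": "integer", "minimum": 1, "default": 900},
    "baseline_range": {
      "type": "array",
      "items": {"type": "number", "exclusiveMinimum": 0},
      "minItems": 2,
      "maxItems": 2,
      "default": [0.5, 0.7],
      "description": "Uniform range (metres) for per-subject baseline left step length."
    },
    "group_fields": {
      "type": "object",
      "description": "Per-group AgentParams overrides: {RPE: {field: value | ['lognormal', median, sigma]}, TE: {...}}. Fields: baseline_sd_m, correction_gain, explore_sd_scale, explore_decay, exploit_shift_sd_scale, washout_retain, washout_decay, recall_bias_pct.",
      "propertyNames": {"enum": ["RPE", "TE"]},
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "oneOf": [
            {"type": "number"},
            {
              "type": "array",
              "prefixItems": [
                {"const": "lognormal"},
                {"type": "number", "exclusiveMinimum": 0},
                {"type": "number", "minimum": 0}
              ],
              "minItems": 3,
              "maxItems": 3
            }
          ]
        }
      }
    },
    "schedule": {
      "type": "object",
      "additionalProperties": false,
      "description": "Overrides for the adaptive target schedule.",
      "properties": {
        "ramp_hold": {"type": "integer", "minimum": 1, "default": 50},
        "step_pct": {"type": "number", "exclusiveMinimum": 0, "default": 1},
        "strides_per_step": {"type": "integer", "minimum": 1, "default": 10},
        "final_pct": {"type": "number", "exclusiveMinimum": 0, "default": 10},
        "half_width_m": {"type": "number", "exclusiveMinimum": 0, "default": 0.02}
      }
    },
    "draws": {"type": "integer", "minimum": 100, "default": 10000, "description": "Posterior draws retained per chain."},
    "chains": {"type": "integer", "minimum": 1, "default": 4},
    "tune": {"type": "integer", "minimum": 0, "default": 1000, "description": "Burn-in ensemble steps discarded per chain."},
    "seed": {"type": "integer", "minimum": 0, "default": 0},
    "out_dir": {"type": "string", "default": "stridelearn_run"}
  }
}
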