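{
  "$defs": {
    "AnalysisGoal": {
      "enum": [
        "superiority",
        "non_inferiority"
      ],
      "title": "AnalysisGoal",
      "type": "string"
    },
    "Arm": {
      "description": "One non-control comparison arm.  Control/placebo arms appear only as\ncomparator text; the comparison, not the arm per se, is the unit.",
      "properties": {
        "comparator": {
          "default": "",
          "title": "Comparator",
          "type": "string"
        },
        "treatment_id": {
          "title": "Treatment Id",
          "type": "string"
        }
      },
      "required": [
        "treatment_id"
      ],
      "title": "Arm",
      "type": "object"
    },
    "DiseaseState": {
      "enum": [
        "advanced",
        "regional",
        "localized",
        "resected"
      ],
      "title": "DiseaseState",
      "type": "string"
    },
    "EffectType": {
      "enum": [
        "hazard_ratio",
        "median_survival_difference_months",
        "other"
      ],
      "title": "EffectType",
      "type": "string"
    },
    "Outcome": {
      "description": "Outcomes in scope.  The first release tracks overall survival only.",
      "enum": [
        "overall_survival"
      ],
      "title": "Outcome",
      "type": "string"
    },
    "ResultEntry": {
      "description": "The curated result for one (arm, timepoint, subgroup, goal) cell.",
      "properties": {
        "effect_size": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Effect Size"
        },
        "effect_type": {
          "anyOf": [
            {
              "$ref": "#/$defs/EffectType"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "failed_due_to_toxicity": {
          "default": false,
          "title": "Failed Due To Toxicity",
          "type": "boolean"
        },
        "significant_after_correction": {
          "title": "Significant After Correction",
          "type": "boolean"
        }
      },
      "required": [
        "significant_after_correction"
      ],
      "title": "ResultEntry",
      "type": "object"
    },
    "TherapeuticGoal": {
      "enum": [
        "become_disease_free",
        "stop_progression",
        "shrink_or_slow",
        "symptom_relief"
      ],
      "title": "TherapeuticGoal",
      "type": "string"
    }
  },
  "description": "A structured study description ready for disaggregation.\n\n``results`` is keyed by the combination index string\n``\"<arm>.<timepoint>.<subgroup>.<goal>\"`` (0-based); a cell may be the\nliteral ``\"not_reported\"`` to suppress that combination.",
  "properties": {
    "analysis_goals": {
      "items": {
        "$ref": "#/$defs/AnalysisGoal"
      },
      "title": "Analysis Goals",
      "type": "array"
    },
    "arms": {
      "items": {
        "$ref": "#/$defs/Arm"
      },
      "title": "Arms",
      "type": "array"
    },
    "disease_state": {
      "$ref": "#/$defs/DiseaseState"
    },
    "group_evidence": {
      "default": false,
      "title": "Group Evidence",
      "type": "boolean"
    },
    "group_size": {
      "default": 1,
      "title": "Group Size",
      "type": "integer"
    },
    "outcome": {
      "$ref": "#/$defs/Outcome",
      "default": "overall_survival"
    },
    "ref_id": {
      "title": "Ref Id",
      "type": "string"
    },
    "results": {
      "additionalProperties": {
        "anyOf": [
          {
            "$ref": "#/$defs/ResultEntry"
          },
          {
            "const": "not_reported",
            "type": "string"
          }
        ]
      },
      "title": "Results",
      "type": "object"
    },
    "subgroups": {
      "items": {
        "items": {
          "type": "string"
        },
        "type": "array"
      },
      "title": "Subgroups",
      "type": "array"
    },
    "therapeutic_goal": {
      "$ref": "#/$defs/TherapeuticGoal"
    },
    "timepoints": {
      "items": {
        "type": "string"
      },
      "title": "Timepoints",
      "type": "array"
    }
  },
  "required": [
    "ref_id",
    "arms",
    "disease_state",
    "therapeutic_goal"
  ],
  "title": "StudySpec",
  "type": "object"
}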