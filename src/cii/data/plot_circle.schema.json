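{
  "description": "One treatment's presence in one matrix square at a given date.",
  "properties": {
    "as_of_date": {
      "format": "date",
      "title": "As Of Date",
      "type": "string"
    },
    "cumulative_weight": {
      "title": "Cumulative Weight",
      "type": "number"
    },
    "modality_colour": {
      "title": "Modality Colour",
      "type": "string"
    },
    "shade_tier": {
      "title": "Shade Tier",
      "type": "integer"
    },
    "size_class": {
      "title": "Size Class",
      "type": "string"
    },
    "square": {
      "title": "Square",
      "type": "string"
    },
    "treatment_id": {
      "title": "Treatment Id",
      "type": "string"
    }
  },
  "required": [
    "treatment_id",
    "square",
    "modality_colour",
    "shade_tier",
    "size_class",
    "cumulative_weight",
    "as_of_date"
  ],
  "title": "PlotCircle",
  "type": "object"
}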