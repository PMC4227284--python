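{
  "name": "MEWS",
  "version": "subbe-2001",
  "provenance": "Modified Early Warning Score. Transcribed from Subbe et al., QJM 2001;94:521-526. Five bedside components; consciousness scored directly on the AVPU scale.",
  "total_range": [0, 14],
  "normal_floor": 0,
  "components": [
    {
      "name": "systolic_bp", "unit": "mmHg", "direction": "both",
      "bands": [
        {"lo": null, "hi": 71, "points": 3},
        {"lo": 71, "hi": 81, "points": 2},
        {"lo": 81, "hi": 101, "points": 1},
        {"lo": 101, "hi": 200, "points": 0},
        {"lo": 200, "hi": null, "points": 2}
      ]
    },
    {
      "name": "heart_rate", "unit": "beats/min", "direction": "both",
      "bands": [
        {"lo": null, "hi": 41, "points": 2},
        {"lo": 41, "hi": 51, "points": 1},
        {"lo": 51, "hi": 101, "points": 0},
        {"lo": 101, "hi": 111, "points": 1},
        {"lo": 111, "hi": 130, "points": 2},
        {"lo": 130, "hi": null, "points": 3}
      ]
    },
    {
      "name": "respiratory_rate", "unit": "breaths/min", "direction": "both",
      "bands": [
        {"lo": null, "hi": 9, "points": 2},
        {"lo": 9, "hi": 15, "points": 0},
        {"lo": 15, "hi": 21, "points": 1},
        {"lo": 21, "hi": 30, "points": 2},
        {"lo": 30, "hi": null, "points": 3}
      ]
    },
    {
      "name": "temperature", "unit": "degC", "direction": "both",
      "bands": [
        {"lo": null, "hi": 35.0, "points": 2},
        {"lo": 35.0, "hi": 38.5, "points": 0},
        {"lo": 38.5, "hi": null, "points": 2}
      ]
    }
  ],
  "special_terms": [
    {"name": "consciousness", "kind": "categorical", "component": "avpu",
     "map": {"A": 0, "V": 1, "P": 2, "U": 3}}
  ]
}
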