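{
  "name": "ViEWS",
  "version": "prytherch-2010",
  "provenance": "VitalPac Early Warning Score. Transcribed from Prytherch et al., Resuscitation 2010;81:932-937. Seven components including any supplemental oxygen (3 points) and AVPU (any impairment scores 3).",
  "total_range": [0, 21],
  "normal_floor": 0,
  "components": [
    {
      "name": "heart_rate", "unit": "beats/min", "direction": "both",
      "bands": [
        {"lo": null, "hi": 41, "points": 3},
        {"lo": 41, "hi": 51, "points": 1},
        {"lo": 51, "hi": 91, "points": 0},
        {"lo": 91, "hi": 111, "points": 1},
        {"lo": 111, "hi": 131, "points": 2},
        {"lo": 131, "hi": null, "points": 3}
      ]
    },
    {
      "name": "respiratory_rate", "unit": "breaths/min", "direction": "both",
      "bands": [
        {"lo": null, "hi": 9, "points": 3},
        {"lo": 9, "hi": 12, "points": 1},
        {"lo": 12, "hi": 21, "points": 0},
        {"lo": 21, "hi": 25, "points": 2},
        {"lo": 25, "hi": null, "points": 3}
      ]
    },
    {
      "name": "temperature", "unit": "degC", "direction": "both",
      "bands": [
        {"lo": null, "hi": 35.1, "points": 3},
        {"lo": 35.1, "hi": 36.1, "points": 1},
        {"lo": 36.1, "hi": 38.1, "points": 0},
        {"lo": 38.1, "hi": 39.1, "points": 1},
        {"lo": 39.1, "hi": null, "points": 2}
      ]
    },
    {
      "name": "systolic_bp", "unit": "mmHg", "direction": "both",
      "bands": [
        {"lo": null, "hi": 91, "points": 3},
        {"lo": 91, "hi": 101, "points": 2},
        {"lo": 101, "hi": 111, "points": 1},
        {"lo": 111, "hi": 250, "points": 0},
        {"lo": 250, "hi": null, "points": 3}
      ]
    },
    {
      "name": "spo2", "unit": "%", "direction": "low",
      "bands": [
        {"lo": null, "hi": 92, "points": 3},
        {"lo": 92, "hi": 94, "points": 2},
        {"lo": 94, "hi": 96, "points": 1},
        {"lo": 96, "hi": null, "points": 0}
      ]
    }
  ],
  "special_terms": [
    {"name": "supplemental_oxygen", "kind": "flag", "component": "supplemental_o2", "points": 3},
    {"name": "consciousness", "kind": "categorical", "component": "avpu",
     "map": {"A": 0, "V": 3, "P": 3, "U": 3}}
  ]
}
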