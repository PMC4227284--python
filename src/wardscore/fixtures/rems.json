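{
  "name": "REMS",
  "version": "olsson-2004",
  "provenance": "Rapid Emergency Medicine Score. Transcribed from Olsson, Terent & Lind, J Intern Med 2004;255:579-587. Six components: age, mean arterial pressure, heart rate, respiratory rate, oxygen saturation, Glasgow Coma Scale.",
  "total_range": [0, 26],
  "normal_floor": 0,
  "components": [
    {
      "name": "map", "unit": "mmHg", "direction": "both",
      "bands": [
        {"lo": null, "hi": 50, "points": 4},
        {"lo": 50, "hi": 70, "points": 2},
        {"lo": 70, "hi": 110, "points": 0},
        {"lo": 110, "hi": 130, "points": 2},
        {"lo": 130, "hi": 160, "points": 3},
        {"lo": 160, "hi": null, "points": 4}
      ]
    },
    {
      "name": "heart_rate", "unit": "beats/min", "direction": "both",
      "bands": [
        {"lo": null, "hi": 40, "points": 4},
        {"lo": 40, "hi": 55, "points": 3},
        {"lo": 55, "hi": 70, "points": 2},
        {"lo": 70, "hi": 110, "points": 0},
        {"lo": 110, "hi": 140, "points": 2},
        {"lo": 140, "hi": 180, "points": 3},
        {"lo": 180, "hi": null, "points": 4}
      ]
    },
    {
      "name": "respiratory_rate", "unit": "breaths/min", "direction": "both",
      "bands": [
        {"lo": null, "hi": 6, "points": 4},
        {"lo": 6, "hi": 10, "points": 2},
        {"lo": 10, "hi": 12, "points": 1},
        {"lo": 12, "hi": 25, "points": 0},
        {"lo": 25, "hi": 35, "points": 1},
        {"lo": 35, "hi": 50, "points": 3},
        {"lo": 50, "hi": null, "points": 4}
      ]
    },
    {
      "name": "spo2", "unit": "%", "direction": "low",
      "bands": [
        {"lo": null, "hi": 75, "points": 4},
        {"lo": 75, "hi": 86, "points": 3},
        {"lo": 86, "hi": 90, "points": 1},
        {"lo": 90, "hi": null, "points": 0}
      ]
    },
    {
      "name": "gcs", "unit": "points", "direction": "low",
      "bands": [
        {"lo": null, "hi": 5, "points": 4},
        {"lo": 5, "hi": 8, "points": 3},
        {"lo": 8, "hi": 11, "points": 2},
        {"lo": 11, "hi": 14, "points": 1},
        {"lo": 14, "hi": null, "points": 0}
      ]
    }
  ],
  "special_terms": [
    {"name": "age_points", "kind": "bands", "component": "age", "direction": "high",
     "bands": [
       {"lo": null, "hi": 45, "points": 0},
       {"lo": 45, "hi": 55, "points": 2},
       {"lo": 55, "hi": 65, "points": 3},
       {"lo": 65, "hi": 75, "points": 5},
       {"lo": 75, "hi": null, "points": 6}
     ]}
  ]
}
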