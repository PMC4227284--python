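{
  "name": "SCS",
  "version": "kellett-2006-reconstructed",
  "provenance": "Simple Clinical Score, after Kellett & Deane, QJM 2006;99:771-781. The SCS mixes bedside physiology with functional and historical items. Cut-points and weights here are a documented reconstruction in the spirit of the source (the exact printed table was not available for transcription); items that are not charted for ward patients (breathlessness, abnormal ECG, inability to stand, new stroke) default to 0 = normal, mirroring how the score degrades when functional-status data are not collected. The declared range is the published 0-32 maximum; this reconstruction attains at most 26.",
  "total_range": [0, 32],
  "normal_floor": 0,
  "components": [
    {
      "name": "heart_rate", "unit": "beats/min", "direction": "high",
      "bands": [
        {"lo": null, "hi": 100, "points": 0},
        {"lo": 100, "hi": 130, "points": 1},
        {"lo": 130, "hi": null, "points": 2}
      ]
    },
    {
      "name": "systolic_bp", "unit": "mmHg", "direction": "low",
      "bands": [
        {"lo": null, "hi": 80, "points": 3},
        {"lo": 80, "hi": 100, "points": 2},
        {"lo": 100, "hi": null, "points": 0}
      ]
    },
    {
      "name": "respiratory_rate", "unit": "breaths/min", "direction": "high",
      "bands": [
        {"lo": null, "hi": 20, "points": 0},
        {"lo": 20, "hi": 30, "points": 1},
        {"lo": 30, "hi": null, "points": 3}
      ]
    },
    {
      "name": "temperature", "unit": "degC", "direction": "low",
      "bands": [
        {"lo": null, "hi": 35.0, "points": 2},
        {"lo": 35.0, "hi": null, "points": 0}
      ]
    },
    {
      "name": "spo2", "unit": "%", "direction": "low",
      "bands": [
        {"lo": null, "hi": 90, "points": 2},
        {"lo": 90, "hi": 94, "points": 1},
        {"lo": 94, "hi": null, "points": 0}
      ]
    }
  ],
  "special_terms": [
    {"name": "age_points", "kind": "bands", "component": "age", "direction": "high",
     "bands": [
       {"lo": null, "hi": 50, "points": 0},
       {"lo": 50, "hi": 70, "points": 1},
       {"lo": 70, "hi": null, "points": 2}
     ]},
    {"name": "consciousness", "kind": "categorical", "component": "avpu",
     "map": {"A": 0, "V": 1, "P": 4, "U": 4}},
    {"name": "diabetes", "kind": "flag", "component": "diabetes", "points": 1},
    {"name": "nursing_home_resident", "kind": "flag", "component": "nursing_home", "points": 1},
    {"name": "breathless_on_presentation", "kind": "flag", "component": "breathless", "points": 1},
    {"name": "abnormal_ecg", "kind": "flag", "component": "abnormal_ecg", "points": 1},
    {"name": "unable_to_stand", "kind": "flag", "component": "unable_to_stand", "points": 2},
    {"name": "new_stroke", "kind": "flag", "component": "new_stroke", "points": 2}
  ]
}
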