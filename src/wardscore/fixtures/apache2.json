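{
  "name": "APACHE2",
  "version": "knaus-1985",
  "provenance": "Acute Physiology and Chronic Health Evaluation II. Transcribed from Knaus et al., Crit Care Med 1985;13:818-829. Twelve acute-physiology variables (worst in the window) plus age and chronic-health points. Oxygenation uses A-aDO2 when FiO2 >= 0.5, else PaO2. Neurologic points are 15 minus GCS. Creatinine points are not doubled for acute renal failure (ARF adjudication is not available from ward charts). Chronic-health points: 5 for a nonoperative admission with documented severe organ insufficiency or immunocompromise, approximated here by chronic liver disease, HIV, or metastatic cancer on the comorbidity list.",
  "total_range": [0, 71],
  "normal_floor": 0,
  "components": [
    {
      "name": "temperature", "unit": "degC", "direction": "both",
      "bands": [
        {"lo": null, "hi": 30.0, "points": 4},
        {"lo": 30.0, "hi": 32.0, "points": 3},
        {"lo": 32.0, "hi": 34.0, "points": 2},
        {"lo": 34.0, "hi": 36.0, "points": 1},
        {"lo": 36.0, "hi": 38.5, "points": 0},
        {"lo": 38.5, "hi": 39.0, "points": 1},
        {"lo": 39.0, "hi": 41.0, "points": 3},
        {"lo": 41.0, "hi": null, "points": 4}
      ]
    },
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
      "name": "ph", "unit": "pH", "direction": "both",
      "bands": [
        {"lo": null, "hi": 7.15, "points": 4},
        {"lo": 7.15, "hi": 7.25, "points": 3},
        {"lo": 7.25, "hi": 7.33, "points": 2},
        {"lo": 7.33, "hi": 7.5, "points": 0},
        {"lo": 7.5, "hi": 7.6, "points": 1},
        {"lo": 7.6, "hi": 7.7, "points": 3},
        {"lo": 7.7, "hi": null, "points": 4}
      ]
    },
    {
      "name": "sodium", "unit": "mmol/L", "direction": "both",
      "bands": [
        {"lo": null, "hi": 111, "points": 4},
        {"lo": 111, "hi": 120, "points": 3},
        {"lo": 120, "hi": 130, "points": 2},
        {"lo": 130, "hi": 150, "points": 0},
        {"lo": 150, "hi": 155, "points": 1},
        {"lo": 155, "hi": 160, "points": 2},
        {"lo": 160, "hi": 180, "points": 3},
        {"lo": 180, "hi": null, "points": 4}
      ]
    },
    {
      "name": "potassium", "unit": "mmol/L", "direction": "both",
      "bands": [
        {"lo": null, "hi": 2.5, "points": 4},
        {"lo": 2.5, "hi": 3.0, "points": 2},
        {"lo": 3.0, "hi": 3.5, "points": 1},
        {"lo": 3.5, "hi": 5.5, "points": 0},
        {"lo": 5.5, "hi": 6.0, "points": 1},
        {"lo": 6.0, "hi": 7.0, "points": 3},
        {"lo": 7.0, "hi": null, "points": 4}
      ]
    },
    {
      "name": "creatinine", "unit": "mg/dL", "direction": "both",
      "bands": [
        {"lo": null, "hi": 0.6, "points": 2},
        {"lo": 0.6, "hi": 1.5, "points": 0},
        {"lo": 1.5, "hi": 2.0, "points": 2},
        {"lo": 2.0, "hi": 3.5, "points": 3},
        {"lo": 3.5, "hi": null, "points": 4}
      ]
    },
    {
      "name": "hematocrit", "unit": "%", "direction": "both",
      "bands": [
        {"lo": null, "hi": 20, "points": 4},
        {"lo": 20, "hi": 30, "points": 2},
        {"lo": 30, "hi": 46, "points": 0},
        {"lo": 46, "hi": 50, "points": 1},
        {"lo": 50, "hi": 60, "points": 2},
        {"lo": 60, "hi": null, "points": 4}
      ]
    },
    {
      "name": "wbc", "unit": "10^3/uL", "direction": "both",
      "bands": [
        {"lo": null, "hi": 1.0, "points": 4},
        {"lo": 1.0, "hi": 3.0, "points": 2},
        {"lo": 3.0, "hi": 15.0, "points": 0},
        {"lo": 15.0, "hi": 20.0, "points": 1},
        {"lo": 20.0, "hi": 40.0, "points": 2},
        {"lo": 40.0, "hi": null, "points": 4}
      ]
    }
  ],
  "special_terms": [
    {"name": "oxygenation", "kind": "hook", "hook": "apache2_oxygenation", "max_points": 4},
    {"name": "neurologic", "kind": "hook", "hook": "gcs_deficit", "max_points": 12},
    {"name": "age_points", "kind": "bands", "component": "age", "direction": "high",
     "bands": [
       {"lo": null, "hi": 45, "points": 0},
       {"lo": 45, "hi": 55, "points": 2},
       {"lo": 55, "hi": 65, "points": 3},
       {"lo": 65, "hi": 75, "points": 5},
       {"lo": 75, "hi": null, "points": 6}
     ]},
    {"name": "chronic_health", "kind": "hook", "hook": "apache2_chronic_health", "max_points": 5,
     "flags": ["chronic_liver_disease", "hiv", "metastatic"]}
  ]
}
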