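{
  "name": "SAPS2",
  "version": "legall-1993",
  "provenance": "Simplified Acute Physiology Score II. Transcribed from Le Gall, Lemeshow & Saulnier, JAMA 1993;270:2957-2963. Serum urea bands expressed as BUN in mg/dL. The PaO2/FiO2 term applies only to ventilated or CPAP patients and therefore scores 0 on wards; urine output is not charted on wards and is treated as normal (0 points). Admission type for this cohort is medical (6 points), giving a ward floor of 6.",
  "total_range": [0, 163],
  "normal_floor": 6,
  "components": [
    {
      "name": "heart_rate", "unit": "beats/min", "direction": "both",
      "bands": [
        {"lo": null, "hi": 40, "points": 11},
        {"lo": 40, "hi": 70, "points": 2},
        {"lo": 70, "hi": 120, "points": 0},
        {"lo": 120, "hi": 160, "points": 4},
        {"lo": 160, "hi": null, "points": 7}
      ]
    },
    {
      "name": "systolic_bp", "unit": "mmHg", "direction": "both",
      "bands": [
        {"lo": null, "hi": 70, "points": 13},
        {"lo": 70, "hi": 100, "points": 5},
        {"lo": 100, "hi": 200, "points": 0},
        {"lo": 200, "hi": null, "points": 2}
      ]
    },
    {
      "name": "temperature", "unit": "degC", "direction": "high",
      "bands": [
        {"lo": null, "hi": 39.0, "points": 0},
        {"lo": 39.0, "hi": null, "points": 3}
      ]
    },
    {
      "name": "bun", "unit": "mg/dL", "direction": "high",
      "bands": [
        {"lo": null, "hi": 28, "points": 0},
        {"lo": 28, "hi": 84, "points": 6},
        {"lo": 84, "hi": null, "points": 10}
      ]
    },
    {
      "name": "wbc", "unit": "10^3/uL", "direction": "both",
      "bands": [
        {"lo": null, "hi": 1.0, "points": 12},
        {"lo": 1.0, "hi": 20.0, "points": 0},
        {"lo": 20.0, "hi": null, "points": 3}
      ]
    },
    {
      "name": "potassium", "unit": "mmol/L", "direction": "both",
      "bands": [
        {"lo": null, "hi": 3.0, "points": 3},
        {"lo": 3.0, "hi": 5.0, "points": 0},
        {"lo": 5.0, "hi": null, "points": 3}
      ]
    },
    {
      "name": "sodium", "unit": "mmol/L", "direction": "both",
      "bands": [
        {"lo": null, "hi": 125, "points": 5},
        {"lo": 125, "hi": 145, "points": 0},
        {"lo": 145, "hi": null, "points": 1}
      ]
    },
    {
      "name": "bicarbonate", "unit": "mmol/L", "direction": "low",
      "bands": [
        {"lo": null, "hi": 15, "points": 6},
        {"lo": 15, "hi": 20, "points": 3},
        {"lo": 20, "hi": null, "points": 0}
      ]
    },
    {
      "name": "bilirubin", "unit": "mg/dL", "direction": "high",
      "bands": [
        {"lo": null, "hi": 4.0, "points": 0},
        {"lo": 4.0, "hi": 6.0, "points": 4},
        {"lo": 6.0, "hi": null, "points": 9}
      ]
    },
    {
      "name": "gcs", "unit": "points", "direction": "low",
      "bands": [
        {"lo": null, "hi": 6, "points": 26},
        {"lo": 6, "hi": 9, "points": 13},
        {"lo": 9, "hi": 11, "points": 7},
        {"lo": 11, "hi": 14, "points": 5},
        {"lo": 14, "hi": null, "points": 0}
      ]
    }
  ],
  "special_terms": [
    {"name": "age_points", "kind": "bands", "component": "age", "direction": "high",
     "bands": [
       {"lo": null, "hi": 40, "points": 0},
       {"lo": 40, "hi": 60, "points": 7},
       {"lo": 60, "hi": 70, "points": 12},
       {"lo": 70, "hi": 75, "points": 15},
       {"lo": 75, "hi": 80, "points": 16},
       {"lo": 80, "hi": null, "points": 18}
     ]},
    {"name": "oxygenation_if_ventilated", "kind": "hook", "hook": "saps2_oxygenation", "max_points": 11},
    {"name": "admission_type", "kind": "categorical", "component": "admission_type",
     "map": {"scheduled_surgical": 0, "medical": 6, "unscheduled_surgical": 8}},
    {"name": "metastatic_cancer", "kind": "flag", "component": "metastatic", "points": 9},
    {"name": "aids", "kind": "flag", "component": "hiv", "points": 17}
  ]
}
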