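{
  "name": "PIRO",
  "version": "howell-2011-reconstructed",
  "provenance": "Predisposition / Infection / Response / Organ dysfunction staging for emergency-department patients with suspected infection, after Howell et al., Crit Care Med 2011;39:322-327. Weights are a documented reconstruction of the ED-derived variant (the exact printed table was not available for transcription): predisposition from age and comorbidity, infection from source (pneumonia carries risk), response from tachypnea / tachycardia / bandemia, organ dysfunction from hypotension, azotemia, hypoxemia, thrombocytopenia and lactate.",
  "total_range": [0, 21],
  "normal_floor": 0,
  "components": [
    {
      "name": "respiratory_rate", "unit": "breaths/min", "direction": "high",
      "bands": [
        {"lo": null, "hi": 20, "points": 0},
        {"lo": 20, "hi": null, "points": 1}
      ]
    },
    {
      "name": "heart_rate", "unit": "beats/min", "direction": "high",
      "bands": [
        {"lo": null, "hi": 120, "points": 0},
        {"lo": 120, "hi": null, "points": 1}
      ]
    },
    {
      "name": "band_fraction", "unit": "%", "direction": "high",
      "bands": [
        {"lo": null, "hi": 5.0, "points": 0},
        {"lo": 5.0, "hi": null, "points": 1}
      ]
    },
    {
      "name": "systolic_bp", "unit": "mmHg", "direction": "low",
      "bands": [
        {"lo": null, "hi": 90, "points": 2},
        {"lo": 90, "hi": null, "points": 0}
      ]
    },
    {
      "name": "bun", "unit": "mg/dL", "direction": "high",
      "bands": [
        {"lo": null, "hi": 40, "points": 0},
        {"lo": 40, "hi": null, "points": 1}
      ]
    },
    {
      "name": "spo2", "unit": "%", "direction": "low",
      "bands": [
        {"lo": null, "hi": 90, "points": 1},
        {"lo": 90, "hi": null, "points": 0}
      ]
    },
    {
      "name": "platelets", "unit": "10^3/uL", "direction": "low",
      "bands": [
        {"lo": null, "hi": 150, "points": 1},
        {"lo": 150, "hi": null, "points": 0}
      ]
    },
    {
      "name": "lactate", "unit": "mmol/L", "direction": "high",
      "bands": [
        {"lo": null, "hi": 4.0, "points": 0},
        {"lo": 4.0, "hi": null, "points": 2}
      ]
    }
  ],
  "special_terms": [
    {"name": "age_points", "kind": "bands", "component": "age", "direction": "high",
     "bands": [
       {"lo": null, "hi": 65, "points": 0},
       {"lo": 65, "hi": 80, "points": 1},
       {"lo": 80, "hi": null, "points": 2}
     ]},
    {"name": "nursing_home_resident", "kind": "flag", "component": "nursing_home", "points": 2},
    {"name": "malignancy", "kind": "flag", "component": "malignancy", "points": 2},
    {"name": "chronic_liver_disease", "kind": "flag", "component": "chronic_liver_disease", "points": 1},
    {"name": "chronic_heart_failure", "kind": "flag", "component": "chf", "points": 1},
    {"name": "chronic_pulmonary_disease", "kind": "flag", "component": "chronic_pulmonary_disease", "points": 1},
    {"name": "pneumonia_source", "kind": "flag", "component": "pneumonia", "points": 2}
  ]
}
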