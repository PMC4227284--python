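{
  "name": "SOFA",
  "version": "vincent-1996",
  "provenance": "Sequential Organ Failure Assessment. Transcribed from Vincent et al., Intensive Care Med 1996;22:707-710. Six organ systems scored 0-4. Respiratory points are assigned from the PaO2/FiO2 ratio without the ventilatory-support requirement for grades 3-4 (ward patients are unventilated; with the assume-normal PaO2 the component scores 0 when no blood gas exists). Cardiovascular combines hypotension (MAP < 70 mmHg) with vasopressor dose via a max rule; ward patients receive no vasopressors so the component is 0/1 in practice. Renal scored on creatinine only (urine output not charted on wards).",
  "total_range": [0, 24],
  "normal_floor": 0,
  "components": [
    {
      "name": "pao2_fio2_ratio", "unit": "mmHg", "direction": "low",
      "bands": [
        {"lo": null, "hi": 100, "points": 4},
        {"lo": 100, "hi": 200, "points": 3},
        {"lo": 200, "hi": 300, "points": 2},
        {"lo": 300, "hi": 400, "points": 1},
        {"lo": 400, "hi": null, "points": 0}
      ]
    },
    {
      "name": "platelets", "unit": "10^3/uL", "direction": "low",
      "bands": [
        {"lo": null, "hi": 20, "points": 4},
        {"lo": 20, "hi": 50, "points": 3},
        {"lo": 50, "hi": 100, "points": 2},
        {"lo": 100, "hi": 150, "points": 1},
        {"lo": 150, "hi": null, "points": 0}
      ]
    },
    {
      "name": "bilirubin", "unit": "mg/dL", "direction": "high",
      "bands": [
        {"lo": null, "hi": 1.2, "points": 0},
        {"lo": 1.2, "hi": 2.0, "points": 1},
        {"lo": 2.0, "hi": 6.0, "points": 2},
        {"lo": 6.0, "hi": 12.0, "points": 3},
        {"lo": 12.0, "hi": null, "points": 4}
      ]
    },
    {
      "name": "gcs", "unit": "points", "direction": "low",
      "bands": [
        {"lo": null, "hi": 6, "points": 4},
        {"lo": 6, "hi": 10, "points": 3},
        {"lo": 10, "hi": 13, "points": 2},
        {"lo": 13, "hi": 15, "points": 1},
        {"lo": 15, "hi": null, "points": 0}
      ]
    },
    {
      "name": "creatinine", "unit": "mg/dL", "direction": "high",
      "bands": [
        {"lo": null, "hi": 1.2, "points": 0},
        {"lo": 1.2, "hi": 2.0, "points": 1},
        {"lo": 2.0, "hi": 3.5, "points": 2},
        {"lo": 3.5, "hi": 5.0, "points": 3},
        {"lo": 5.0, "hi": null, "points": 4}
      ]
    }
  ],
  "special_terms": [
    {"name": "cardiovascular", "kind": "hook", "hook": "sofa_cardiovascular", "max_points": 4}
  ]
}
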