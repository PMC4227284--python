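{
  "name": "MEDS",
  "version": "shapiro-2003",
  "provenance": "Mortality in Emergency Department Sepsis score. Transcribed from Shapiro et al., Crit Care Med 2003;31:670-675. Nine weighted predictors; largely baseline/categorical, which is why the score decays slowly over the pre-event window. Terminal illness is approximated by metastatic cancer; lower respiratory infection by a pneumonia source; altered mental status by any AVPU impairment; septic shock by severe sepsis with hypotension (SBP < 90 mmHg).",
  "total_range": [0, 27],
  "normal_floor": 0,
  "components": [
    {
      "name": "platelets", "unit": "10^3/uL", "direction": "low",
      "bands": [
        {"lo": null, "hi": 150, "points": 3},
        {"lo": 150, "hi": null, "points": 0}
      ]
    },
    {
      "name": "band_fraction", "unit": "%", "direction": "high",
      "bands": [
        {"lo": null, "hi": 5.0, "points": 0},
        {"lo": 5.0, "hi": null, "points": 3}
      ]
    }
  ],
  "special_terms": [
    {"name": "terminal_illness", "kind": "flag", "component": "metastatic", "points": 6},
    {"name": "tachypnea_or_hypoxia", "kind": "hook", "hook": "meds_tachypnea_hypoxia", "max_points": 3},
    {"name": "septic_shock", "kind": "hook", "hook": "meds_septic_shock", "max_points": 3},
    {"name": "age_points", "kind": "bands", "component": "age", "direction": "high",
     "bands": [
       {"lo": null, "hi": 66, "points": 0},
       {"lo": 66, "hi": null, "points": 3}
     ]},
    {"name": "lower_respiratory_infection", "kind": "flag", "component": "pneumonia", "points": 2},
    {"name": "nursing_home_resident", "kind": "flag", "component": "nursing_home", "points": 2},
    {"name": "altered_mental_status", "kind": "categorical", "component": "avpu",
     "map": {"A": 0, "V": 2, "P": 2, "U": 2}}
  ]
}
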