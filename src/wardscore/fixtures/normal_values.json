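{
  "_comment": "Single source of truth for 'normal' physiology: the midpoint used both by the assume-normal imputation rule and as the baseline mean of the synthetic cohort generator. Each midpoint is chosen to score the minimum in every scoring system that uses the component. 'worse' is the direction of derangement used for drift simulation and worst-value tie-breaking; 'sd' is the between/within-patient spread used by the generator; 'lo'/'hi' are plausibility truncation bounds.",
  "heart_rate": {"normal": 75.0, "sd": 11.0, "worse": "high", "lo": 20.0, "hi": 250.0, "unit": "beats/min"},
  "respiratory_rate": {"normal": 14.0, "sd": 2.0, "worse": "high", "lo": 4.0, "hi": 70.0, "unit": "breaths/min"},
  "systolic_bp": {"normal": 115.0, "sd": 12.0, "worse": "low", "lo": 40.0, "hi": 280.0, "unit": "mmHg"},
  "diastolic_bp": {"normal": 70.0, "sd": 8.0, "worse": "low", "lo": 20.0, "hi": 160.0, "unit": "mmHg"},
  "map": {"normal": 85.0, "sd": 9.0, "worse": "low", "lo": 30.0, "hi": 200.0, "unit": "mmHg"},
  "temperature": {"normal": 37.0, "sd": 0.45, "worse": "high", "lo": 28.0, "hi": 43.0, "unit": "degC"},
  "spo2": {"normal": 97.5, "sd": 1.4, "worse": "low", "lo": 50.0, "hi": 100.0, "unit": "%"},
  "fio2": {"normal": 0.21, "sd": 0.0, "worse": "high", "lo": 0.21, "hi": 1.0, "unit": "fraction"},
  "gcs": {"normal": 15.0, "sd": 0.0, "worse": "low", "lo": 3.0, "hi": 15.0, "unit": "points"},
  "wbc": {"normal": 7.5, "sd": 2.0, "worse": "high", "lo": 0.1, "hi": 120.0, "unit": "10^3/uL"},
  "platelets": {"normal": 250.0, "sd": 55.0, "worse": "low", "lo": 3.0, "hi": 1200.0, "unit": "10^3/uL"},
  "bilirubin": {"normal": 0.7, "sd": 0.25, "worse": "high", "lo": 0.05, "hi": 40.0, "unit": "mg/dL"},
  "creatinine": {"normal": 0.9, "sd": 0.2, "worse": "high", "lo": 0.2, "hi": 20.0, "unit": "mg/dL"},
  "bun": {"normal": 14.0, "sd": 4.0, "worse": "high", "lo": 1.0, "hi": 250.0, "unit": "mg/dL"},
  "sodium": {"normal": 140.0, "sd": 2.8, "worse": "low", "lo": 100.0, "hi": 190.0, "unit": "mmol/L"},
  "potassium": {"normal": 4.2, "sd": 0.35, "worse": "high", "lo": 1.2, "hi": 10.0, "unit": "mmol/L"},
  "bicarbonate": {"normal": 24.0, "sd": 2.0, "worse": "low", "lo": 4.0, "hi": 50.0, "unit": "mmol/L"},
  "hematocrit": {"normal": 40.0, "sd": 3.5, "worse": "low", "lo": 9.0, "hi": 70.0, "unit": "%"},
  "glucose": {"normal": 100.0, "sd": 18.0, "worse": "high", "lo": 20.0, "hi": 1200.0, "unit": "mg/dL"},
  "albumin": {"normal": 4.0, "sd": 0.35, "worse": "low", "lo": 0.8, "hi": 6.0, "unit": "g/dL"},
  "lactate": {"normal": 1.0, "sd": 0.35, "worse": "high", "lo": 0.2, "hi": 30.0, "unit": "mmol/L"},
  "band_fraction": {"normal": 2.0, "sd": 1.5, "worse": "high", "lo": 0.0, "hi": 60.0, "unit": "%"},
  "pao2": {"normal": 90.0, "sd": 8.0, "worse": "low", "lo": 25.0, "hi": 600.0, "unit": "mmHg"},
  "paco2": {"normal": 40.0, "sd": 3.5, "worse": "high", "lo": 10.0, "hi": 130.0, "unit": "mmHg"},
  "ph": {"normal": 7.4, "sd": 0.03, "worse": "low", "lo": 6.5, "hi": 8.0, "unit": "pH"},
  "pao2_fio2_ratio": {"normal": 428.6, "sd": 40.0, "worse": "low", "lo": 30.0, "hi": 700.0, "unit": "mmHg"}
}
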