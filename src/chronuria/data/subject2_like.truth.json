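{
  "baseline_rate": 10.0,
  "circadian": [
    0.1,
    15.0
  ],
  "creatinine_cv": 0.1,
  "creatinine_day": 0.85,
  "creatinine_night": 1.11,
  "day_multiplier": 1.15,
  "inversion_target": 0.1957480508973503,
  "noise_cv": [
    0.15,
    0.25
  ],
  "seed": 224737,
  "semiseptan": [
    0.18,
    90.0,
    -60.0
  ],
  "start_clock": 8.0,
  "volume_cv": 0.12,
  "volume_day": 850.0,
  "volume_night": 650.0
}
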