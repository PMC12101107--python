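{
  "baseline_rate": 17.0,
  "circadian": [
    0.15,
    14.0
  ],
  "creatinine_cv": 0.1,
  "creatinine_day": 0.75,
  "creatinine_night": 1.36,
  "day_multiplier": 1.5,
  "inversion_target": 0.06099195628842774,
  "noise_cv": [
    0.18,
    0.3
  ],
  "seed": 104729,
  "semiseptan": [
    0.3,
    90.0,
    -80.0
  ],
  "start_clock": 8.0,
  "volume_cv": 0.12,
  "volume_day": 950.0,
  "volume_night": 525.0
}
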