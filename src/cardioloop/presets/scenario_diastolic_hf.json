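{
 "description": "diastolic left heart failure: LV basal passive elastance 0.05 -> 0.12 mmHg/ml",
 "name": "diastolic_hf",
 "patches": {
  "chambers.lv.e_min": 0.12
 }
}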