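{
 "description": "systolic left heart failure: LV max elastance 2.8 -> 1.0 mmHg/ml",
 "name": "systolic_hf",
 "patches": {
  "chambers.lv.e_max": 1.0
 }
}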