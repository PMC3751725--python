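{
 "description": "stiff vasculature: Young's modulus 3000 -> 6000 mmHg in every segment",
 "name": "arteriosclerosis",
 "patches": {
  "globals.young_modulus": 6000.0
 }
}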