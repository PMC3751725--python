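{
 "description": "open aortic valve area 5.0 -> 0.7 cm^2",
 "name": "aortic_stenosis",
 "patches": {
  "valves.aortic.a_max": 0.7
 }
}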