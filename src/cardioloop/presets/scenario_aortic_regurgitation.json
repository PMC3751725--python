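{
 "description": "closed aortic valve area 0.0 -> 0.2 cm^2",
 "name": "aortic_regurgitation",
 "patches": {
  "valves.aortic.a_min": 0.2
 }
}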