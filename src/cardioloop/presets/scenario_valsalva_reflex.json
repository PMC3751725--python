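{
 "description": "Valsalva maneuver with the baroreceptor reflex on",
 "name": "valsalva_reflex",
 "patches": {
  "baroreflex.enabled": true
 },
 "timed_events": [
  {
   "path": "globals.intrathoracic_pressure",
   "t_end": 40.0,
   "t_start": 20.0,
   "value": 10.0
  }
 ]
}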