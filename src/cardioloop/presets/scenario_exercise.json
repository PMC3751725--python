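{
 "description": "final exercise stage: HR +100%, biventricular contractility +50%, systemic and pulmonary arteriolar diameters +50% (contraction timing scales with the square root of the rate factor)",
 "name": "exercise",
 "patches": {
  "chambers.lv.e_max": {
   "scale": 1.5
  },
  "chambers.rv.e_max": {
   "scale": 1.5
  },
  "globals.heart_rate": 144.0,
  "segments.left_arterioles.r0": {
   "scale": 1.5
  },
  "segments.pulm_arterioles.r0": {
   "scale": 1.5
  },
  "segments.right_arterioles.r0": {
   "scale": 1.5
  },
  "segments.sys_arterioles.r0": {
   "scale": 1.5
  }
 }
}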