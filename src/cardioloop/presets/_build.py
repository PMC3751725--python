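"""Generator for the shipped preset files.

The baseline segment dimensions are not all published; each segment is
specified here by its hemodynamic working point (contained volume, base
resistance, compliance, normal mean pressure) — reconstructed from standard
adult physiology and calibrated so the normal run reproduces the published
normal-physiology output table — and inverted to a concrete geometry
(length, radius, thickness, parallel-vessel count) through the Poiseuille /
thin-wall relations.  Run ``python -m cardioloop.presets._build`` to
regenerate the JSON files in place.
"""

from __future__ import annotations

import json
from pathlib import Path

from cardioloop.parameters import ModelConfig
from cardioloop.vascular import geometry_from_targets

ETA = 0.00024     # mmHg*s
Y_INC = 3000.0    # mmHg

# name, group, p0, volume, R0, C0 (=1/E0), r0 (None -> single vessel),
# provenance, extras
SEGMENT_TARGETS = [
    ("aortic_root", "intrathoracic", 80.0, 25.0, 0.0005, 0.135, None,
     "reconstructed", {}),
    ("ascending_aorta", "intrathoracic", 79.8, 40.0, 0.0006, 0.215, None,
     "reconstructed", {}),
    ("proximal_arch", "intrathoracic", 79.6, 25.0, 0.0005, 0.135, None,
     "reconstructed", {}),
    ("distal_arch", "intrathoracic", 79.5, 30.0, 0.0007, 0.150, None,
     "reconstructed", {}),
    ("descending_aorta", "intrathoracic", 79.2, 60.0, 0.0015, 0.29, None,
     "reconstructed", {}),
    ("peripheral_artery", "extrathoracic", 78.5, 100.0, 0.008, 0.49, 0.2,
     "reconstructed", {}),
    ("sys_arterioles", "extrathoracic", 52.0, 35.0, 0.98, 0.15, 0.008,
     "calibrated", {"baroreflex_target": True}),
    ("sys_capillaries", "extrathoracic", 18.0, 250.0, 0.10, 2.5, 4e-4,
     "calibrated", {"o2_systemic_sink": True, "init_sat": 68.3}),
    ("sys_veins", "extrathoracic", 5.92, 3235.0, 0.010, 60.0, 0.3,
     "calibrated", {"init_sat": 68.3}),
    ("ivc", "intrathoracic", 4.1, 500.0, 0.003, 12.0, 0.8,
     "reconstructed", {"init_sat": 68.3}),
    ("right_carotid", "extrathoracic", 78.5, 25.0, 0.006, 0.05, 0.3,
     "reconstructed", {}),
    ("right_arterioles", "extrathoracic", 45.0, 10.0, 7.1, 0.04, 0.006,
     "calibrated", {"baroreflex_target": True}),
    ("right_capveins", "extrathoracic", 6.6, 150.0, 0.35, 5.0, 0.02,
     "calibrated", {"o2_systemic_sink": True, "init_sat": 68.3}),
    ("left_carotid", "extrathoracic", 78.5, 25.0, 0.006, 0.05, 0.3,
     "reconstructed", {}),
    ("left_arterioles", "extrathoracic", 45.0, 10.0, 7.1, 0.04, 0.006,
     "calibrated", {"baroreflex_target": True}),
    ("left_capveins", "extrathoracic", 6.6, 150.0, 0.35, 5.0, 0.02,
     "calibrated", {"o2_systemic_sink": True, "init_sat": 68.3}),
    ("svc", "intrathoracic", 4.1, 200.0, 0.012, 7.0, 0.6,
     "reconstructed", {"init_sat": 68.3}),
    ("pulm_artery", "intrathoracic", 11.0, 80.0, 0.001, 3.0, None,
     "reconstructed", {"init_sat": 68.3}),
    ("pulm_arterioles", "intrathoracic", 8.5, 30.0, 0.082, 1.0, 0.01,
     "calibrated", {"init_sat": 68.3}),
    ("pulm_capillaries", "intrathoracic", 7.4, 123.0, 0.010, 2.5, 4e-4,
     "calibrated", {"o2_pulmonary": True, "init_sat": 96.3}),
    ("pulm_small_veins", "intrathoracic", 6.7, 120.0, 0.006, 3.0, 0.02,
     "calibrated", {"init_sat": 96.3}),
    ("pulm_veins", "intrathoracic", 6.3, 220.0, 0.005, 4.0, 0.5,
     "reconstructed", {"init_sat": 96.3}),
    ("left_coronary", "pericardial", 79.0, 8.0, 2.0, 0.03, 0.15,
     "calibrated", {}),
    ("left_cor_micro", "pericardial", 40.0, 12.0, 13.5, 0.10, 0.003,
     "calibrated", {"compression_chamber": "lv", "compression_coef": 0.75,
                    "o2_myocardial": "lv", "init_sat": 40.0}),
    ("right_coronary", "pericardial", 79.0, 4.0, 10.0, 0.015, 0.10,
     "calibrated", {}),
    ("right_cor_micro", "pericardial", 40.0, 6.0, 115.0, 0.05, 0.003,
     "calibrated", {"compression_chamber": "rv", "compression_coef": 0.35,
                    "o2_myocardial": "rv", "init_sat": 40.0}),
]

BRANCHES = [
    # valves
    ("la", "lv"), ("lv", "aortic_root"), ("ra", "rv"), ("rv", "pulm_artery"),
    # systemic trunk
    ("aortic_root", "ascending_aorta"),
    ("ascending_aorta", "proximal_arch"),
    ("proximal_arch", "right_carotid"),
    ("proximal_arch", "distal_arch"),
    ("distal_arch", "left_carotid"),
    ("distal_arch", "descending_aorta"),
    ("descending_aorta", "peripheral_artery"),
    ("peripheral_artery", "sys_arterioles"),
    ("sys_arterioles", "sys_capillaries"),
    ("sys_capillaries", "sys_veins"),
    ("sys_veins", "ivc"),
    ("ivc", "ra"),
    # upper body
    ("right_carotid", "right_arterioles"),
    ("right_arterioles", "right_capveins"),
    ("right_capveins", "svc"),
    ("left_carotid", "left_arterioles"),
    ("left_arterioles", "left_capveins"),
    ("left_capveins", "svc"),
    ("svc", "ra"),
    # pulmonary
    ("pulm_artery", "pulm_arterioles"),
    ("pulm_arterioles", "pulm_capillaries"),
    ("pulm_capillaries", "pulm_small_veins"),
    ("pulm_small_veins", "pulm_veins"),
    ("pulm_veins", "la"),
    # coronary
    ("aortic_root", "left_coronary"),
    ("left_coronary", "left_cor_micro"),
    ("left_cor_micro", "ra"),
    ("aortic_root", "right_coronary"),
    ("right_coronary", "right_cor_micro"),
    ("right_cor_micro", "ra"),
]

CHAMBERS = {
    "la": dict(e_max=0.20, e_min=0.09, v0=20.0, alpha1=0.12, alpha2=0.22,
               n1=1.9, n2=11.0, onset_delay=0.0, r_wall=0.001,
               r_outflow=0.002, starling_v_threshold=130.0,
               starling_width=80.0, phi_passive=100.0, initial_volume=55.0),
    "lv": dict(e_max=2.8, e_min=0.05, v0=0.0, alpha1=0.22, alpha2=0.42,
               n1=3.0, n2=25.0, onset_delay=0.16, r_wall=0.002,
               r_outflow=0.070, starling_v_threshold=180.0,
               starling_width=120.0, phi_passive=300.0, initial_volume=105.0),
    "ra": dict(e_max=0.20, e_min=0.10, v0=18.0, alpha1=0.12, alpha2=0.22,
               n1=1.9, n2=11.0, onset_delay=0.0, r_wall=0.001,
               r_outflow=0.002, starling_v_threshold=140.0,
               starling_width=90.0, phi_passive=110.0, initial_volume=50.0),
    "rv": dict(e_max=0.55, e_min=0.035, v0=0.0, alpha1=0.22, alpha2=0.42,
               n1=3.0, n2=25.0, onset_delay=0.16, r_wall=0.002,
               r_outflow=0.012, starling_v_threshold=220.0,
               starling_width=150.0, phi_passive=300.0, initial_volume=105.0),
}

VALVES = {
    "mitral": dict(a_min=0.0, a_max=9.0, k_open=100.0, k_close=250.0),
    "aortic": dict(a_min=0.0, a_max=5.0, k_open=100.0, k_close=250.0),
    "tricuspid": dict(a_min=0.0, a_max=10.0, k_open=100.0, k_close=250.0),
    "pulmonary": dict(a_min=0.0, a_max=5.0, k_open=100.0, k_close=250.0),
}


def build_baseline() -> ModelConfig:
    segments = []
    for (name, group, p0, vol, r0_res, c0, r_hint, prov,
         extras) in SEGMENT_TARGETS:
        length, r0, h, n = geometry_from_targets(vol, r0_res, c0, ETA, Y_INC,
                                                 r0=r_hint)
        segments.append(dict(name=name, length=length, r0=r0, h=h, n=n,
                             p0=p0, external_group=group, provenance=prov,
                             **extras))
    data = {
        "version": 1,
        "globals": {},
        "chambers": CHAMBERS,
        "valves": VALVES,
        "septum": {"esv0": 10.0, "esa": 20.0},
        "pericardium": {"v_pc0": 755.0, "p_scale": 1.75, "phi": 30.0,
                        "p_min": -2.0, "myocardial_volume": 380.0},
        "segments": segments,
        "branches": [{"source": s, "target": t} for s, t in BRANCHES],
        "shunts": [
            {"name": "asd", "source": "la", "target": "ra", "area": 0.0},
            {"name": "vsd", "source": "lv", "target": "rv", "area": 0.0},
            {"name": "pda", "source": "descending_aorta",
             "target": "pulm_artery", "area": 0.0},
        ],
        "oxygen": {"enabled": True},
        "baroreflex": {"enabled": False},
    }
    return ModelConfig.model_validate(data)


SCENARIOS = {
    "normal": {
        "name": "normal",
        "description": "identity patch; identical to the baseline preset",
        "patches": {},
    },
    "systolic_hf": {
        "name": "systolic_hf",
        "description": "systolic left heart failure: LV max elastance "
                       "2.8 -> 1.0 mmHg/ml",
        "patches": {"chambers.lv.e_max": 1.0},
    },
    "diastolic_hf": {
        "name": "diastolic_hf",
        "description": "diastolic left heart failure: LV basal passive "
                       "elastance 0.05 -> 0.12 mmHg/ml",
        "patches": {"chambers.lv.e_min": 0.12},
    },
    "aortic_stenosis": {
        "name": "aortic_stenosis",
        "description": "open aortic valve area 5.0 -> 0.7 cm^2",
        "patches": {"valves.aortic.a_max": 0.7},
    },
    "aortic_regurgitation": {
        "name": "aortic_regurgitation",
        "description": "closed aortic valve area 0.0 -> 0.2 cm^2",
        "patches": {"valves.aortic.a_min": 0.2},
    },
    "valsalva": {
        "name": "valsalva",
        "description": "intrathoracic pressure 0 -> +10 mmHg for ~20 s, "
                       "baroreflex off",
        "patches": {},
        "timed_events": [{"t_start": 20.0, "t_end": 40.0,
                          "path": "globals.intrathoracic_pressure",
                          "value": 10.0}],
    },
    "valsalva_reflex": {
        "name": "valsalva_reflex",
        "description": "Valsalva maneuver with the baroreceptor reflex on",
        "patches": {"baroreflex.enabled": True},
        "timed_events": [{"t_start": 20.0, "t_end": 40.0,
                          "path": "globals.intrathoracic_pressure",
                          "value": 10.0}],
    },
    "exercise": {
        "name": "exercise",
        "description": "final exercise stage: HR +100%, biventricular "
                       "contractility +50%, systemic and pulmonary "
                       "arteriolar diameters +50% (contraction timing "
                       "scales with the square root of the rate factor)",
        "patches": {
            "globals.heart_rate": 144.0,
            "chambers.lv.e_max": {"scale": 1.5},
            "chambers.rv.e_max": {"scale": 1.5},
            "segments.sys_arterioles.r0": {"scale": 1.5},
            "segments.right_arterioles.r0": {"scale": 1.5},
            "segments.left_arterioles.r0": {"scale": 1.5},
            "segments.pulm_arterioles.r0": {"scale": 1.5},
        },
    },
    "arteriosclerosis": {
        "name": "arteriosclerosis",
        "description": "stiff vasculature: Young's modulus 3000 -> 6000 mmHg "
                       "in every segment",
        "patches": {"globals.young_modulus": 6000.0},
    },
}


def write_presets(outdir=None) -> None:
    outdir = Path(outdir) if outdir else Path(__file__).parent
    cfg = build_baseline()
    (outdir / "baseline.json").write_text(
        json.dumps(cfg.model_dump(by_alias=True), indent=1, sort_keys=True))
    for name, doc in SCENARIOS.items():
        (outdir / f"scenario_{name}.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True))


if __name__ == "__main__":
    write_presets()
    print("presets written")
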