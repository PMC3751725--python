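import warnings

import numpy as np
import pytest

from cardioloop.engine import run
from cardioloop.parameters import ModelConfig, load_preset
from cardioloop.vascular import geometry_from_targets

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def normal_config():
    return load_preset("normal")


@pytest.fixture(scope="session")
def baseline_trace():
    """60 s baseline run shared by conservation/acceptance/oxygen tests."""
    return run(load_preset("normal"), 60.0, record_interval=0.002)


def _scenario_trace(name):
    return run(load_preset(name), 60.0, record_interval=0.002)


@pytest.fixture(scope="session")
def systolic_hf_trace():
    return _scenario_trace("systolic_hf")


@pytest.fixture(scope="session")
def diastolic_hf_trace():
    return _scenario_trace("diastolic_hf")


@pytest.fixture(scope="session")
def aortic_stenosis_trace():
    return _scenario_trace("aortic_stenosis")


@pytest.fixture(scope="session")
def aortic_regurgitation_trace():
    return _scenario_trace("aortic_regurgitation")


@pytest.fixture(scope="session")
def exercise_trace():
    return _scenario_trace("exercise")


def make_two_segment_config(perturbation=0.1, damping_lambda=0.0,
                            r_a=0.05, r_b=0.05, c_a=2.0, c_b=50.0,
                            v_a=100.0, v_b=500.0, p0=20.0):
    """Heart-less two-compartment circuit for Windkessel-decay oracles.

    Segment geometry is inverted from (volume, resistance, compliance)
    targets with a small vessel radius so that inertance is negligible
    (L/R << the relaxation time).  Segment 'a' starts ``perturbation`` ml
    above its reference volume.
    """
    eta, y = 0.00024, 3000.0
    segs = []
    for name, vol, rr, cc in [("a", v_a, r_a, c_a), ("b", v_b, r_b, c_b)]:
        length, r0, h, n = geometry_from_targets(vol, rr, cc, eta, y, r0=0.02)
        segs.append(dict(name=name, length=length, r0=r0, h=h, n=n, p0=p0))
    segs[0]["initial_volume"] = v_a + perturbation
    data = {
        "globals": {"blood_volume": v_a + v_b + perturbation,
                    "damping_lambda": damping_lambda},
        "segments": segs,
        "branches": [{"source": "a", "target": "b"}],
        "oxygen": {"enabled": False},
    }
    return ModelConfig.model_validate(data)


def rel_err(value, reference):
    return abs(value - reference) / abs(reference)


def assert_within(value, reference, rel, label=""):
    assert rel_err(value, reference) <= rel, (
        f"{label}: {value:.4g} vs expected {reference:.4g} "
        f"(> {100 * rel:.0f}% off)")
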