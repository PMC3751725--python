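"""Typed parameter model, validation and preset handling.

The full model configuration is a nested pydantic document that can be
round-tripped through JSON.  Scenario overrides are small patch documents
(dotted parameter paths to new values, plus optional timed events applied by
the solver during a run).  A versioned preset directory ships the calibrated
baseline man and the pathology/maneuver scenarios.
"""

from __future__ import annotations

import copy
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, ValidationError, model_validator

__all__ = [
    "GlobalParams",
    "ChamberParams",
    "SeptumParams",
    "PericardiumParams",
    "ValveParams",
    "SegmentParams",
    "BranchParams",
    "ShuntParams",
    "OxygenParams",
    "BaroreflexParams",
    "EcgParams",
    "TimedEvent",
    "ScenarioOverride",
    "ModelConfig",
    "load_config",
    "write_config",
    "load_preset",
    "load_scenario",
    "list_presets",
    "apply_scenario",
    "get_path",
    "set_path",
]

ExternalGroup = Literal["extrathoracic", "intrathoracic", "pericardial"]


class GlobalParams(BaseModel):
    """System-wide constants (clinical units, see :mod:`cardioloop.units`)."""

    blood_volume: float = Field(5600.0, gt=0.0, description="ml")
    blood_viscosity: float = Field(0.00024, gt=0.0, description="mmHg*s")
    blood_density: float = Field(1.060, gt=0.0, description="g/cm^3")
    heart_rate: float = Field(72.0, gt=0.0, description="min^-1")
    dt: float = Field(0.00025, gt=0.0, description="s")
    hb: float = Field(140.0, gt=0.0, description="g/l")
    vo2_systemic: float = Field(250.0, ge=0.0, description="ml O2/min")
    pulm_cap_sat: float = Field(99.4, ge=0.0, le=100.0, description="%")
    pulm_shunt_fraction: float = Field(0.10, ge=0.0, le=1.0)
    young_modulus: float = Field(3000.0, gt=0.0, description="mmHg")
    damping_lambda: float = Field(0.5, ge=0.0, le=1.0)
    intrathoracic_pressure: float = Field(0.0, description="mmHg")


class ChamberParams(BaseModel):
    e_max: float = Field(..., gt=0.0, description="mmHg/ml")
    e_min: float = Field(..., gt=0.0, description="mmHg/ml")
    v0: float = Field(..., ge=0.0, description="ml, unstressed volume")
    alpha1: float = Field(..., gt=0.0, description="cycle fraction")
    alpha2: float = Field(..., gt=0.0, description="cycle fraction")
    n1: float = Field(..., gt=0.0)
    n2: float = Field(..., gt=0.0)
    onset_delay: float = Field(0.0, ge=0.0, description="s")
    r_wall: float = Field(0.0, ge=0.0, description="mmHg*s/ml")
    r_outflow: float = Field(0.0, ge=0.0, description="mmHg*s/ml")
    starling_v_threshold: float = Field(..., gt=0.0, description="ml")
    starling_width: float = Field(..., gt=0.0, description="ml")
    phi_passive: float = Field(..., gt=0.0, description="ml")
    v0_passive: Optional[float] = Field(
        None, ge=0.0,
        description="zero-crossing volume of the passive curve, ml; below "
                    "it the relaxed chamber sucks (defaults to v0)")
    initial_volume: float = Field(..., gt=0.0, description="ml")

    @model_validator(mode="after")
    def _emax_ge_emin(self):
        if self.e_max < self.e_min:
            raise ValueError("e_max must be >= e_min")
        return self


class SeptumParams(BaseModel):
    esv0: float = Field(..., gt=0.0, description="dimensionless, scales elv(t)")
    esa: float = Field(..., gt=0.0, description="mmHg/ml, atrial septum")


class PericardiumParams(BaseModel):
    v_pc0: float = Field(..., gt=0.0, description="ml")
    p_scale: float = Field(..., gt=0.0, description="mmHg")
    phi: float = Field(..., gt=0.0, description="ml")
    p_min: float = Field(..., description="mmHg, may be negative")
    myocardial_volume: float = Field(380.0, ge=0.0, description="ml")


class ValveParams(BaseModel):
    a_min: float = Field(0.0, ge=0.0, description="cm^2, closed area")
    a_max: float = Field(..., gt=0.0, description="cm^2, open area")
    k_open: float = Field(..., gt=0.0, description="1/(mmHg*s)")
    k_close: float = Field(..., gt=0.0, description="1/(mmHg*s)")

    @model_validator(mode="after")
    def _areas_ordered(self):
        if self.a_min > self.a_max:
            raise ValueError("a_min must be <= a_max")
        return self


class SegmentParams(BaseModel):
    """Geometry and anchoring of one lumped vascular compartment.

    ``provenance`` records whether the dimensions were reconstructed from the
    cited anatomy or calibrated to reproduce the normal-physiology output
    tables (the supplementary per-segment tables are not in the main text).
    """

    name: str
    length: float = Field(..., gt=0.0, description="cm")
    r0: float = Field(..., gt=0.0, description="cm, radius at p0")
    h: float = Field(..., gt=0.0, description="cm, wall thickness")
    n: float = Field(..., gt=0.0, description="parallel vessels")
    p0: float = Field(..., gt=0.0, description="mmHg, normal mean pressure")
    external_group: ExternalGroup = "extrathoracic"
    compression_chamber: Optional[str] = Field(
        None, description="chamber whose pressure compresses this segment")
    compression_coef: float = Field(0.0, ge=0.0)
    initial_volume: Optional[float] = Field(
        None, gt=0.0, description="ml; defaults to the reference volume")
    init_sat: Optional[float] = Field(
        None, ge=0.0, le=100.0, description="initial O2 saturation, %")
    baroreflex_target: bool = Field(
        False, description="resistance is scaled by the baroreflex")
    o2_systemic_sink: bool = Field(
        False, description="systemic VO2 is extracted from this bed")
    o2_myocardial: Optional[Literal["lv", "rv"]] = Field(
        None, description="myocardial VO2 of this ventricle is extracted here")
    o2_pulmonary: bool = Field(
        False, description="pulmonary oxygenation happens in this segment")
    provenance: str = Field("calibrated", description="reconstructed|calibrated")


class BranchParams(BaseModel):
    """Directed flow connection between two named compartments."""

    source: str
    target: str


class ShuntParams(BaseModel):
    name: str
    source: str
    target: str
    area: float = Field(0.0, ge=0.0, description="cm^2")
    gorlin_c: float = Field(1.0, gt=0.0)
    g: float = Field(980.0, gt=0.0, description="cm/s^2")


class OxygenParams(BaseModel):
    enabled: bool = True
    pva_a: float = Field(1.8e-5, ge=0.0, description="ml O2 per mmHg*ml")
    pva_b: float = Field(0.0024, ge=0.0, description="ml O2 per (mmHg/ml) per 100 g")
    pva_c: float = Field(0.022, ge=0.0, description="ml O2 basal per beat per 100 g")
    lv_mass: float = Field(150.0, gt=0.0, description="g")
    rv_mass: float = Field(70.0, gt=0.0, description="g")
    init_arterial_sat: float = Field(96.2, ge=0.0, le=100.0)
    init_venous_sat: float = Field(68.3, ge=0.0, le=100.0)


class BaroreflexParams(BaseModel):
    enabled: bool = False
    setpoint: float = Field(79.0, gt=0.0, description="mmHg")
    gain_hr: float = Field(0.025, description="per mmHg")
    gain_emax: float = Field(0.02, description="per mmHg")
    gain_res: float = Field(0.03, description="per mmHg")
    time_constant: float = Field(2.0, gt=0.0, description="s")
    limit_lo: float = Field(0.5, gt=0.0, lt=1.0)
    limit_hi: float = Field(2.0, gt=1.0)
    sense_segment: str = Field("ascending_aorta",
                               description="pressure-sensing compartment")


class EcgParams(BaseModel):
    weights: dict[str, float] = Field(
        default_factory=lambda: {"la": 0.15, "lv": 1.0, "ra": 0.1, "rv": 0.35})
    delay: float = Field(0.06, ge=0.0, description="s, electromechanical delay")


class TimedEvent(BaseModel):
    """Set ``path`` to ``value`` at t_start, restore the original at t_end."""

    t_start: float = Field(..., ge=0.0)
    t_end: float = Field(..., gt=0.0)
    path: str
    value: Union[float, dict]

    @model_validator(mode="after")
    def _ordered(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        return self


class ScenarioOverride(BaseModel):
    name: str
    description: str = ""
    #: dotted parameter path -> absolute value, or {"scale": factor}
    patches: dict[str, Union[float, bool, dict]] = Field(default_factory=dict)
    timed_events: list[TimedEvent] = Field(default_factory=list)
    #: staged patches applied at given times during the run (path -> value)
    staged: list[dict] = Field(default_factory=list)


class ModelConfig(BaseModel):
    """Complete, validated parameter set for one simulation."""

    version: int = 1
    globals_: GlobalParams = Field(default_factory=GlobalParams, alias="globals")
    chambers: Optional[dict[str, ChamberParams]] = None
    valves: Optional[dict[str, ValveParams]] = None
    septum: Optional[SeptumParams] = None
    pericardium: Optional[PericardiumParams] = None
    segments: list[SegmentParams] = Field(default_factory=list)
    branches: list[BranchParams] = Field(default_factory=list)
    shunts: list[ShuntParams] = Field(default_factory=list)
    oxygen: OxygenParams = Field(default_factory=OxygenParams)
    baroreflex: BaroreflexParams = Field(default_factory=BaroreflexParams)
    ecg: EcgParams = Field(default_factory=EcgParams)
    timed_events: list[TimedEvent] = Field(default_factory=list)
    staged: list[dict] = Field(default_factory=list)

    model_config = {"populate_by_name": True}

    @model_validator(mode="after")
    def _check_topology(self):
        names = {s.name for s in self.segments}
        if len(names) != len(self.segments):
            raise ValueError("duplicate segment names")
        if self.chambers is not None:
            missing = {"la", "lv", "ra", "rv"} - set(self.chambers)
            if missing:
                raise ValueError(f"missing chambers: {sorted(missing)}")
            missing_v = {"mitral", "aortic", "tricuspid", "pulmonary"} - set(
                self.valves or {})
            if missing_v:
                raise ValueError(f"missing valves: {sorted(missing_v)}")
            names |= {"la", "lv", "ra", "rv"}
        for br in self.branches:
            for end in (br.source, br.target):
                if end not in names:
                    raise ValueError(f"branch references unknown compartment "
                                     f"'{end}'")
        for sh in self.shunts:
            for end in (sh.source, sh.target):
                if end not in names:
                    raise ValueError(f"shunt references unknown compartment "
                                     f"'{end}'")
        for seg in self.segments:
            if seg.compression_chamber is not None and (
                    self.chambers is None
                    or seg.compression_chamber not in self.chambers):
                raise ValueError(f"segment '{seg.name}' compressed by unknown "
                                 f"chamber '{seg.compression_chamber}'")
        return self

    def segment(self, name: str) -> SegmentParams:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)


# ---------------------------------------------------------------------------
# loading / writing

def load_config(path) -> ModelConfig:
    """Load and validate a configuration from a JSON file."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return ModelConfig.model_validate(data)
    except ValidationError as exc:
        raise ValueError(f"{path}: invalid configuration:\n{exc}") from exc


def write_config(config: ModelConfig, path) -> None:
    Path(path).write_text(
        json.dumps(config.model_dump(by_alias=True), indent=1, sort_keys=True))


def _preset_dir():
    return resources.files("cardioloop") / "presets"


def list_presets() -> list[str]:
    return sorted(p.name[:-5] for p in _preset_dir().iterdir()
                  if p.name.endswith(".json"))


def load_preset(name: str = "normal") -> ModelConfig:
    """Load a shipped preset; scenario presets are applied on the baseline."""
    if name in ("normal", "baseline"):
        data = json.loads((_preset_dir() / "baseline.json").read_text())
        return ModelConfig.model_validate(data)
    return apply_scenario(load_preset("normal"), load_scenario(name))


def load_scenario(name: str) -> ScenarioOverride:
    path = _preset_dir() / f"scenario_{name}.json"
    try:
        text = path.read_text()
    except FileNotFoundError:
        valid = [p[9:] for p in list_presets() if p.startswith("scenario_")]
        raise KeyError(f"unknown scenario '{name}'; valid: baseline, "
                       + ", ".join(valid)) from None
    return ScenarioOverride.model_validate(json.loads(text))


# ---------------------------------------------------------------------------
# path-addressed patching

def _resolve(config: ModelConfig, path: str):
    """Walk a dotted path to (owner object, final attribute/key)."""
    parts = path.split(".")
    obj = config
    for i, part in enumerate(parts[:-1]):
        if part == "globals":
            part = "globals_"
        if isinstance(obj, ModelConfig) and part == "segments":
            obj = obj.segment(parts[i + 1])
            # skip the segment-name component
            return _resolve_tail(obj, parts[i + 2:], path)
        if isinstance(obj, dict):
            if part not in obj:
                raise KeyError(_path_error(config, path))
            obj = obj[part]
        elif isinstance(obj, BaseModel) and part in type(obj).model_fields:
            obj = getattr(obj, part)
        else:
            raise KeyError(_path_error(config, path))
        if obj is None:
            raise KeyError(_path_error(config, path))
    return _resolve_tail(obj, parts[-1:], path)


def _resolve_tail(obj, parts, full_path):
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, BaseModel) and part in type(obj).model_fields:
            obj = getattr(obj, part)
        else:
            raise KeyError(full_path)
    last = parts[-1]
    if last == "globals":
        last = "globals_"
    if isinstance(obj, dict):
        if last not in obj:
            raise KeyError(full_path)
    elif not (isinstance(obj, BaseModel) and last in type(obj).model_fields):
        raise KeyError(full_path)
    return obj, last


def get_path(config: ModelConfig, path: str):
    obj, last = _resolve(config, path)
    return obj[last] if isinstance(obj, dict) else getattr(obj, last)


def set_path(config: ModelConfig, path: str, value) -> None:
    """Set a parameter in place; value may be {"scale": f} for relative."""
    obj, last = _resolve(config, path)
    if isinstance(value, dict):
        if set(value) != {"scale"}:
            raise ValueError(f"patch for '{path}' must be a number or "
                             "{'scale': factor}")
        old = obj[last] if isinstance(obj, dict) else getattr(obj, last)
        value = old * value["scale"]
    if isinstance(obj, dict):
        obj[last] = value
    else:
        setattr(obj, last, value)


def _path_error(config: ModelConfig, path: str) -> str:
    hints = ["globals.<field>", "chambers.<la|lv|ra|rv>.<field>",
             "valves.<mitral|aortic|tricuspid|pulmonary>.<field>",
             "segments.<name>.<field>", "septum.<field>",
             "pericardium.<field>", "oxygen.<field>", "baroreflex.<field>"]
    return f"unknown parameter path '{path}'; valid forms: " + ", ".join(hints)


def apply_scenario(base: ModelConfig,
                   scenario: ScenarioOverride) -> ModelConfig:
    """Return a new configuration with the scenario applied; base unmodified.

    Absolute-value patches are idempotent; ``{"scale": f}`` patches are
    relative.  Timed events and staged patches are attached for the solver to
    apply during the run.
    """
    cfg = copy.deepcopy(base)
    for path, value in scenario.patches.items():
        try:
            set_path(cfg, path, value)
        except KeyError:
            raise KeyError(_path_error(cfg, path)) from None
    cfg.timed_events = list(cfg.timed_events) + list(scenario.timed_events)
    cfg.staged = list(cfg.staged) + list(scenario.staged)
    return ModelConfig.model_validate(cfg.model_dump(by_alias=True))
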