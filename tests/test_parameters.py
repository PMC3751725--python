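import json

import pytest
from pydantic import ValidationError

from cardioloop.parameters import (ModelConfig, ScenarioOverride,
                                   apply_scenario, get_path, list_presets,
                                   load_config, load_preset, load_scenario,
                                   set_path, write_config)


class TestLoad:
    def test_baseline_preset_globals(self, normal_config):
        assert normal_config.globals_.heart_rate == 72.0
        assert normal_config.globals_.blood_volume == 5600.0
        assert normal_config.globals_.damping_lambda == 0.5
        assert normal_config.globals_.dt == pytest.approx(0.00025)

    def test_baseline_topology(self, normal_config):
        assert len(normal_config.segments) == 26
        assert len(normal_config.branches) == 34
        assert normal_config.valves["aortic"].a_max == 5.0
        assert normal_config.chambers["lv"].e_max == 2.8
        assert normal_config.chambers["lv"].e_min == 0.05

    def test_round_trip(self, tmp_path, normal_config):
        path = tmp_path / "cfg.json"
        write_config(normal_config, path)
        again = load_config(path)
        assert again.model_dump() == normal_config.model_dump()

    def test_invalid_json_reports_file(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="not valid JSON"):
            load_config(path)

    def test_negative_dimension_rejected(self, tmp_path, normal_config):
        data = normal_config.model_dump(by_alias=True)
        data["segments"][3]["r0"] = -1.0
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="r0"):
            load_config(path)

    def test_unknown_branch_endpoint_rejected(self, normal_config):
        data = normal_config.model_dump(by_alias=True)
        data["branches"][10]["target"] = "nonexistent"
        with pytest.raises(ValidationError, match="unknown compartment"):
            ModelConfig.model_validate(data)

    def test_presets_ship_all_scenarios(self):
        names = list_presets()
        for scen in ["normal", "systolic_hf", "diastolic_hf",
                     "aortic_stenosis", "aortic_regurgitation", "valsalva",
                     "exercise", "arteriosclerosis"]:
            assert f"scenario_{scen}" in names
        assert "baseline" in names


class TestScenarios:
    def test_empty_override_is_identity(self, normal_config):
        out = apply_scenario(normal_config,
                             ScenarioOverride(name="noop"))
        assert out.model_dump() == normal_config.model_dump()
        assert out is not normal_config

    def test_normal_scenario_matches_baseline(self, normal_config):
        assert (load_preset("normal").model_dump()
                == apply_scenario(normal_config,
                                  load_scenario("normal")).model_dump())

    def test_aortic_stenosis_patch(self, normal_config):
        cfg = apply_scenario(normal_config,
                             load_scenario("aortic_stenosis"))
        assert cfg.valves["aortic"].a_max == 0.7
        assert normal_config.valves["aortic"].a_max == 5.0  # base untouched

    def test_diastolic_hf_patch(self, normal_config):
        cfg = apply_scenario(normal_config, load_scenario("diastolic_hf"))
        assert cfg.chambers["lv"].e_min == 0.12

    def test_absolute_patches_idempotent(self, normal_config):
        scen = load_scenario("systolic_hf")
        once = apply_scenario(normal_config, scen)
        twice = apply_scenario(once, scen)
        assert once.model_dump() == twice.model_dump()

    def test_scale_patch(self, normal_config):
        scen = ScenarioOverride(name="x", patches={
            "segments.sys_arterioles.r0": {"scale": 1.5}})
        base_r0 = normal_config.segment("sys_arterioles").r0
        out = apply_scenario(normal_config, scen)
        assert out.segment("sys_arterioles").r0 == pytest.approx(
            1.5 * base_r0)

    def test_unknown_path_lists_valid_forms(self, normal_config):
        scen = ScenarioOverride(name="x", patches={"chambers.xx.e_max": 1.0})
        with pytest.raises(KeyError, match="valid forms"):
            apply_scenario(normal_config, scen)

    def test_unknown_scenario_name(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            load_scenario("no_such_thing")

    def test_timed_event_ordering_validated(self):
        with pytest.raises(ValidationError):
            ScenarioOverride.model_validate(
                {"name": "bad", "timed_events": [
                    {"t_start": 30.0, "t_end": 20.0,
                     "path": "globals.intrathoracic_pressure",
                     "value": 10.0}]})


class TestPathAccess:
    def test_get_set_round_trip(self, normal_config):
        import copy
        cfg = copy.deepcopy(normal_config)
        assert get_path(cfg, "globals.heart_rate") == 72.0
        set_path(cfg, "chambers.lv.e_max", 1.0)
        assert cfg.chambers["lv"].e_max == 1.0
        set_path(cfg, "septum.esv0", 12.0)
        assert get_path(cfg, "septum.esv0") == 12.0

    def test_segment_path(self, normal_config):
        v = get_path(normal_config, "segments.sys_veins.p0")
        assert v > 0
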