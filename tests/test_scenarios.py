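"""Scenario pipeline: qualitative behaviours, reports, provenance."""

import copy
import json

import numpy as np
import pytest

import thermotrap as tt
from thermotrap.presets import config_hash, default_scenario
from thermotrap.scenarios import (
    run_closed_accumulation,
    run_feed_waste,
    run_feeding_activation,
    run_retention,
    run_scenario,
    run_thickness_scan,
)


def _small_geometry(cfg):
    cfg["geometry"]["n_x"] = 12
    cfg["geometry"]["n_z"] = 48
    return cfg


@pytest.fixture(scope="module")
def small_feeding_cfg():
    cfg = _small_geometry(default_scenario("feeding_activation"))
    for entry in cfg["species"]:
        if entry["S_T_per_K"] == "calibrated":
            entry["S_T_per_K"] = 0.0068
            entry.pop("relative_fold_target", None)
    cfg["duration_h"] = 72.0
    return cfg


class TestClosedAccumulation:
    def test_zero_gradient_gives_unit_folds(self, small_cfg):
        cfg = copy.deepcopy(small_cfg)
        cfg["scenario"] = "closed_accumulation"
        cfg["thermal"] = {"T_cold_C": 33.5, "T_hot_C": 33.5}
        cfg["duration_h"] = 6.0
        rep = run_closed_accumulation(cfg)
        assert rep.metrics["relative_fold_point"] == 1.0
        assert rep.metrics["absolute_fold"] == 1.0
        assert np.isnan(rep.metrics["steady_onset_h"])

    def test_report_metrics_recomputable_from_series(self, small_cfg):
        cfg = copy.deepcopy(small_cfg)
        cfg["scenario"] = "closed_accumulation"
        rep = run_closed_accumulation(cfg)
        df = rep.series["kinetics"]
        bottom = df[(df.species == "sfGFP") & (df.position_mm == 0.5)].sort_values("time_h")
        refold = bottom.concentration_uM.iloc[-1] / bottom.concentration_uM.iloc[0]
        assert refold == pytest.approx(rep.metrics["absolute_fold_transient"], rel=1e-9)


class TestFeedingActivation:
    def test_isothermal_top_rises_then_declines_bottom_stays_low(self, small_feeding_cfg):
        rep = run_feeding_activation(small_feeding_cfg)
        off = rep.metrics["gradient_off"]
        assert off["top_max_uM"] > 0.01  # activated near the feed
        assert off["top_declines_after_peak"]  # then flushed out
        assert off["bottom_max_uM"] < 0.05 * off["top_max_uM"]
        assert rep.qualitative

    def test_gradient_bottom_monotone_and_dominant(self, small_feeding_cfg):
        rep = run_feeding_activation(small_feeding_cfg)
        on = rep.metrics["gradient_on"]
        assert on["bottom_monotone"]
        assert on["bottom_final_uM"] > on["top_final_uM"]

    def test_zero_feed_means_no_synthesis(self, small_feeding_cfg):
        cfg = copy.deepcopy(small_feeding_cfg)
        cfg["flow"]["feed_uM"] = {"feed": 0.0}
        cfg["duration_h"] = 12.0
        rep = run_feeding_activation(cfg)
        for cond in ("gradient_on", "gradient_off"):
            assert rep.metrics[cond]["bottom_max_uM"] < 1e-9
            assert rep.metrics[cond]["top_max_uM"] < 1e-9

    def test_missing_expression_block_rejected(self, small_feeding_cfg):
        cfg = copy.deepcopy(small_feeding_cfg)
        cfg["expression"]["enabled"] = False
        with pytest.raises(ValueError):
            run_feeding_activation(cfg)


class TestFeedWaste:
    def test_pure_washout_when_vmax_zero(self):
        cfg = _small_geometry(default_scenario("feed_waste"))
        cfg["reaction"]["vmax_uM_s"] = 0.0
        cfg["duration_h"] = 200.0
        rep = run_feed_waste(cfg)
        df = rep.series["feed_waste_mass"]
        phos = df[df.species == "phosphate"].sort_values("time_h")
        assert np.all(np.diff(phos.fraction_remaining.to_numpy()) <= 1e-12)

    def test_missing_reaction_block_rejected(self):
        cfg = default_scenario("feed_waste")
        del cfg["reaction"]
        with pytest.raises(ValueError):
            run_feed_waste(cfg)

    def test_atp_accumulates_against_the_flow(self, feed_waste_report):
        assert feed_waste_report.metrics["atp_increasing_to_stable"]
        assert feed_waste_report.metrics["atp_mass_final_pmol"] > 0


class TestThicknessScan:
    def test_zero_gradient_scan_is_flat_at_one(self):
        cfg = _small_geometry(default_scenario("thickness_scan"))
        cfg["thermal"] = {"T_cold_C": 33.5, "T_hot_C": 33.5}
        cfg["species"][0]["S_T_per_K"] = 0.0068
        cfg["thickness_scan"] = {"min_um": 100.0, "max_um": 250.0, "step_um": 75.0}
        cfg["duration_h"] = 2.0
        rep = run_thickness_scan(cfg)
        assert np.allclose(rep.metrics["bottom_fraction_fold"], 1.0, rtol=1e-9)

    def test_empty_scan_rejected(self):
        cfg = default_scenario("thickness_scan")
        cfg["thickness_scan"] = {"min_um": 200.0, "max_um": 100.0, "step_um": 25.0}
        with pytest.raises(ValueError):
            run_thickness_scan(cfg)


class TestRetentionScenario:
    def test_flow_disabled_rejected(self):
        cfg = default_scenario("retention")
        cfg["flow"]["enabled"] = False
        with pytest.raises(ValueError):
            run_retention(cfg)

    def test_waste_ion_removed_faster_than_reporter(self, retention_report):
        """Fast-diffusing phosphate leaves before sfGFP in both conditions."""
        m = retention_report.metrics
        for cond in ("gradient_on", "gradient_off"):
            assert m["phosphate"][cond]["retention_9h"] < m["sfGFP"][cond]["retention_9h"]

    def test_confinement_helps_reporter_in_measured_window(self, retention_report):
        m = retention_report.metrics
        assert (
            m["sfGFP"]["gradient_on"]["retention_9h"]
            >= m["sfGFP"]["gradient_off"]["retention_9h"]
        )


class TestReportPlumbing:
    def test_config_hash_stable_and_sensitive(self):
        cfg = default_scenario("closed_accumulation")
        h1 = config_hash(cfg)
        assert h1 == config_hash(copy.deepcopy(cfg))
        cfg["thermal"]["T_hot_C"] = 41.0
        assert config_hash(cfg) != h1

    def test_report_json_round_trip(self, small_cfg, tmp_path):
        cfg = copy.deepcopy(small_cfg)
        cfg["scenario"] = "closed_accumulation"
        cfg["duration_h"] = 2.0
        rep = run_closed_accumulation(cfg)
        path = tmp_path / "report.json"
        rep.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["scenario"] == "closed_accumulation"
        assert payload["metrics"]["relative_fold_point"] == pytest.approx(
            rep.metrics["relative_fold_point"]
        )
        rep.write_series(tmp_path)
        assert (tmp_path / "kinetics.csv").exists()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            run_scenario({"scenario": "warp_drive"})

    def test_yaml_round_trip_preserves_hash(self, tmp_path):
        cfg = default_scenario("feed_waste")
        path = tmp_path / "cfg.yaml"
        tt.dump_scenario(cfg, path)
        assert config_hash(tt.load_scenario(path)) == config_hash(cfg)
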