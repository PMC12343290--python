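"""The six in-silico experiments, each a config-driven run with a report.

* ``closed_accumulation`` -- closed trap, gradient on: accumulation kinetics
  of the reporter protein, time to steady state, relative (BOT/TOP) and
  absolute (BOT_final/BOT_start) fold statistics.
* ``retention`` -- pre-accumulated (gradient on) or uniform (gradient off)
  initial state challenged by a top-channel water flow: retention curves of
  the reporter and a fast-diffusing waste ion.
* ``feeding_activation`` -- qualitative: a deficient reaction mix fed the
  limiting component from the top; expression switches on where the feed
  accumulates.
* ``feed_waste`` -- ATP fed at the top, converted to phosphate by
  Michaelis-Menten kinetics throughout the trap; reports when total
  phosphate reaches a stable production/removal balance.
* ``thickness_scan`` -- gap-width scan of the 16 h bottom-third accumulation
  (the thermogravitational optimum).
* ``isothermal_relaxation`` -- gradient switched off after accumulation;
  diffusion-only decay to uniformity.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .build import build as build_scenario
from .observables import (
    absolute_accumulation,
    freeze_fractions,
    relative_accumulation,
    retention_at,
)
from .presets import config_hash, default_scenario
from .reactions import ExpressionSpec, ReactionSpec, mm_rate
from .transport import (
    SolverSettings,
    TransportState,
    initial_state,
    point_sample,
    steady_state,
    total_mass,
)

SIX_MONTHS_H = 4392.0  # 183 days


@dataclass
class ScenarioReport:
    """Headline metrics plus provenance for one scenario run."""

    scenario: str
    metrics: dict
    config_hash: str
    seed: int | None = None
    solver: dict = field(default_factory=dict)
    qualitative: bool = False
    series: dict = field(default_factory=dict, repr=False)  # name -> DataFrame

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": 1,
            "scenario": self.scenario,
            "metrics": self.metrics,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "solver": self.solver,
            "qualitative": self.qualitative,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def write_series(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.series.items():
            df.to_csv(outdir / f"{name}.csv", index=False)


def _solver_info(comps) -> dict:
    return {
        "dt_init_s": comps.settings.dt_init_s,
        "dt_max_s": comps.settings.dt_max_s,
        "scheme": comps.settings.scheme,
        "grid": [comps.geometry.n_x, comps.geometry.n_z],
    }


def _gradient_off_cfg(cfg: dict) -> dict:
    """Same scenario with both plates at the mean temperature (Delta T = 0)."""
    out = copy.deepcopy(cfg)
    T_mean = 0.5 * (cfg["thermal"]["T_cold_C"] + cfg["thermal"]["T_hot_C"])
    out["thermal"] = {"T_cold_C": T_mean, "T_hot_C": T_mean}
    return out


def _closed_cfg(cfg: dict) -> dict:
    out = copy.deepcopy(cfg)
    out["flow"] = {"enabled": False}
    return out


def _resolve_calibrated(cfg: dict) -> dict:
    """Replace 'calibrated' Soret entries by their numeric values once.

    Gradient-off or geometry-modified variants of a scenario must reuse the
    coefficients calibrated under the reference gradient, so the resolution
    happens against the unmodified configuration.
    """
    comps = build_scenario(_closed_cfg(cfg))
    out = copy.deepcopy(cfg)
    for entry in out["species"]:
        entry["S_T_per_K"] = comps.species[entry["name"]].S_T_per_K
    return out


def run_closed_accumulation(cfg: dict | None = None) -> ScenarioReport:
    """Closed-trap accumulation: onset time, steady folds, kinetics series."""
    cfg = cfg or default_scenario("closed_accumulation")
    comps = build_scenario(_closed_cfg(cfg))
    obs = cfg["observables"]
    name = cfg["species"][0]["name"]
    sys = comps.system()
    state0 = initial_state(comps.geometry, comps.species_list)
    c0 = comps.species[name].c0_uM

    steady = steady_state(comps.operators[name], init=state0)
    bot_steady = point_sample(steady, name, obs["bottom_um"], obs["window_um"])

    series, final = sys.run(
        state0,
        cfg["duration_h"] * 3600.0,
        comps.settings,
        record_positions_um=(obs["bottom_um"], obs["top_um"]),
        window_um=obs["window_um"],
    )
    bot = series.sample_series(name, obs["bottom_um"])
    if comps.thermal.delta_T == 0:
        onset_h = float("nan")  # no accumulation, no steady-state onset
        rel_point = rel_thirds = abs_fold = 1.0
    else:
        crossed = np.nonzero(bot >= 0.95 * bot_steady)[0]
        onset_h = float(series.times_h[crossed[0]]) if len(crossed) else float("inf")
        rel_point = relative_accumulation(
            steady, name, "point", obs["bottom_um"], obs["top_um"], obs["window_um"]
        )
        rel_thirds = freeze_fractions(steady, name).relative_accumulation
        abs_fold = bot_steady / c0
    metrics = {
        "species": name,
        "steady_onset_h": onset_h,
        "relative_fold_point": float(rel_point),
        "relative_fold_thirds": float(rel_thirds),
        "absolute_fold": float(abs_fold),
        "absolute_fold_transient": float(absolute_accumulation(series, name, obs["bottom_um"])),
        "bottom_steady_uM": float(bot_steady),
        "S_T_per_K": comps.species[name].S_T_per_K,
        "D_um2_s": comps.species[name].D_um2_s,
    }
    return ScenarioReport(
        "closed_accumulation",
        metrics,
        config_hash(cfg),
        cfg.get("seed"),
        _solver_info(comps),
        series={"kinetics": series.to_dataframe()},
    )


def _preaccumulated_state(cfg: dict, hours: float) -> TransportState:
    """Closed-trap, gradient-on run from uniform for the given incubation time."""
    comps = build_scenario(_closed_cfg(cfg))
    sys = comps.system()
    state = initial_state(comps.geometry, comps.species_list)
    _, final = sys.run(state, hours * 3600.0, comps.settings)
    return final


def run_retention(cfg: dict | None = None) -> ScenarioReport:
    """Retention under top-channel flow, gradient on vs off, per species."""
    cfg = cfg or default_scenario("retention")
    if not cfg.get("flow", {}).get("enabled"):
        raise ValueError("retention scenario requires an enabled flow block")
    cfg = _resolve_calibrated(cfg)
    duration_h = cfg["duration_h"]
    times_h = cfg.get("retention_times_h", [9.0, SIX_MONTHS_H])
    pre_h = cfg.get("preaccumulate_h", 16.0)

    curves = {}
    metrics: dict = {"retention_times_h": list(times_h)}
    series_frames = {}
    for condition in ("gradient_on", "gradient_off"):
        cond_cfg = cfg if condition == "gradient_on" else _gradient_off_cfg(cfg)
        comps = build_scenario(cond_cfg)
        if condition == "gradient_on":
            start = _preaccumulated_state(cond_cfg, pre_h)
        else:
            start = initial_state(comps.geometry, comps.species_list)  # uniform (expressed only)
        # attach the (initially water-filled) channel
        flow_state = initial_state(
            comps.geometry, comps.species_list, bc=next(iter(comps.bc.values()))
        )
        flow_state.c = {k: v.copy() for k, v in start.c.items()}
        sys = comps.system()
        series, _ = sys.run(flow_state, duration_h * 3600.0, comps.settings)
        series_frames[f"retention_{condition}"] = series.retention_dataframe()
        for name in comps.species:
            curves[(condition, name)] = series
            metrics.setdefault(name, {})[condition] = {
                f"retention_{t:g}h": retention_at(series, name, t) for t in times_h
            }
    return ScenarioReport(
        "retention",
        metrics,
        config_hash(cfg),
        cfg.get("seed"),
        _solver_info(build_scenario(cfg)),
        series=series_frames,
    )


def run_feeding_activation(cfg: dict | None = None) -> ScenarioReport:
    """Qualitative feeding scenario: activation where the fed component accumulates."""
    cfg = cfg or default_scenario("feeding_activation")
    if not cfg.get("expression", {}).get("enabled"):
        raise ValueError("feeding scenario requires an enabled expression block")
    cfg = _resolve_calibrated(cfg)
    expr = ExpressionSpec(**cfg["expression"])
    obs = cfg["observables"]
    metrics: dict = {}
    frames = {}
    for condition in ("gradient_on", "gradient_off"):
        cond_cfg = cfg if condition == "gradient_on" else _gradient_off_cfg(cfg)
        comps = build_scenario(cond_cfg)
        sys = comps.system(expression=expr)
        state = initial_state(
            comps.geometry, comps.species_list, bc=next(iter(comps.bc.values()))
        )
        series, _ = sys.run(
            state,
            cfg["duration_h"] * 3600.0,
            comps.settings,
            record_positions_um=(obs["bottom_um"], obs["top_um"]),
            window_um=obs["window_um"],
        )
        frames[f"kinetics_{condition}"] = series.to_dataframe()
        bot = series.sample_series(expr.product, obs["bottom_um"])
        top = series.sample_series(expr.product, obs["top_um"])
        metrics[condition] = {
            "bottom_final_uM": float(bot[-1]),
            "bottom_max_uM": float(bot.max()),
            "top_final_uM": float(top[-1]),
            "top_max_uM": float(top.max()),
            "top_declines_after_peak": bool(top[-1] < 0.9 * top.max()),
            "bottom_monotone": bool(np.all(np.diff(bot) >= -1e-12)),
        }
    return ScenarioReport(
        "feeding_activation",
        metrics,
        config_hash(cfg),
        cfg.get("seed"),
        _solver_info(build_scenario(cfg)),
        qualitative=True,
        series=frames,
    )


def run_feed_waste(cfg: dict | None = None) -> ScenarioReport:
    """ATP feed / phosphate waste with Michaelis-Menten conversion.

    The stable state is declared at the first time after which the absolute
    rate of change of total trap phosphate stays below 1% of the reference
    production rate (the MM rate at the feed concentration over the trap).
    """
    cfg = cfg or default_scenario("feed_waste")
    if "reaction" not in cfg:
        raise ValueError("feed/waste scenario requires a reaction block")
    comps = build_scenario(cfg)
    reaction = ReactionSpec(**cfg["reaction"])
    sub, prod = reaction.substrate, reaction.product
    sys = comps.system(reaction=reaction)
    state = initial_state(comps.geometry, comps.species_list, bc=comps.bc[sub])
    series, final = sys.run(state, cfg["duration_h"] * 3600.0, comps.settings)

    feed_uM = comps.bc[sub].feed_uM
    ref_rate_pmol_h = float(mm_rate(feed_uM, reaction)) * comps.geometry.trap_volume_ul * 3600.0
    t_h = series.times_h
    mass_p = series.trap_mass_pmol[prod]
    # rate of change on a uniform grid (the adaptive dt ladder makes raw
    # finite differences noisy at step-size changes)
    t_u = np.linspace(t_h[0], t_h[-1], max(int(t_h[-1] - t_h[0]), 10) + 1)
    dmdt = np.gradient(np.interp(t_u, t_h, mass_p), t_u)  # pmol/h
    below = np.abs(dmdt) < 0.01 * ref_rate_pmol_h
    stable_h = float("inf")
    run_end = np.nonzero(~below)[0]
    if below[-1]:
        i0 = 0 if len(run_end) == 0 else run_end[-1] + 1
        stable_h = float(t_u[i0])
    mass_atp = series.trap_mass_pmol[sub]
    horizon = stable_h if np.isfinite(stable_h) else t_h[-1]
    in_window = t_h <= horizon
    metrics = {
        "stable_state_h": stable_h,
        "reference_production_pmol_h": ref_rate_pmol_h,
        "phosphate_mass_initial_pmol": float(mass_p[0]),
        "phosphate_mass_final_pmol": float(mass_p[-1]),
        "atp_mass_final_pmol": float(mass_atp[-1]),
        "atp_increasing_to_stable": bool(np.all(np.diff(mass_atp[in_window]) > 0)),
    }
    frames = {
        "feed_waste_mass": series.retention_dataframe(),
        "feed_waste_kinetics": series.to_dataframe(),
    }
    return ScenarioReport(
        "feed_waste", metrics, config_hash(cfg), cfg.get("seed"), _solver_info(comps), series=frames
    )


def run_thickness_scan(cfg: dict | None = None) -> ScenarioReport:
    """Bottom-third accumulation vs gap thickness at a fixed 16 h horizon."""
    cfg = cfg or default_scenario("thickness_scan")
    scan = cfg.get("thickness_scan")
    if not scan:
        raise ValueError("thickness scan requires a thickness_scan block")
    thicknesses = np.arange(scan["min_um"], scan["max_um"] + 0.5 * scan["step_um"], scan["step_um"])
    if len(thicknesses) == 0:
        raise ValueError("empty thickness scan")
    cfg = _resolve_calibrated(cfg)  # species coefficients fixed at the reference gap
    name = cfg["species"][0]["name"]
    c0 = float(cfg["species"][0]["c0_uM"])
    folds = []
    for w in thicknesses:
        wcfg = copy.deepcopy(cfg)
        wcfg["geometry"]["gap_um"] = float(w)
        comps = build_scenario(_closed_cfg(wcfg))
        sys = comps.system()
        state = initial_state(comps.geometry, comps.species_list)
        _, final = sys.run(state, cfg["duration_h"] * 3600.0, comps.settings)
        folds.append(freeze_fractions(final, name).bot_uM / c0)
    folds = np.asarray(folds)
    best = int(np.argmax(folds))
    metrics = {
        "thickness_um": thicknesses.tolist(),
        "bottom_fraction_fold": folds.tolist(),
        "optimum_thickness_um": float(thicknesses[best]),
        "optimum_fold": float(folds[best]),
        "horizon_h": cfg["duration_h"],
    }
    import pandas as pd

    frame = pd.DataFrame({"thickness_um": thicknesses, "bottom_fraction_fold": folds})
    return ScenarioReport(
        "thickness_scan",
        metrics,
        config_hash(cfg),
        cfg.get("seed"),
        _solver_info(build_scenario(_closed_cfg(cfg))),
        series={"thickness_scan": frame},
    )


def run_isothermal_relaxation(cfg: dict | None = None) -> ScenarioReport:
    """Diffusion-only decay of an accumulated profile after the gradient is off."""
    cfg = cfg or default_scenario("isothermal_relaxation")
    cfg = _resolve_calibrated(cfg)
    T_iso = cfg.get("isothermal_T_C", 27.0)
    tol = cfg.get("uniformity_tol", 0.05)
    pre_h = cfg.get("preaccumulate_h", 18.0)
    obs = cfg["observables"]
    name = cfg["species"][0]["name"]

    start = _preaccumulated_state(cfg, pre_h)

    def relax(T_C: float, duration_h: float):
        comps = build_scenario(_closed_cfg(cfg), isothermal_T_C=T_C)
        sys = comps.system()
        state = start.copy()
        state.time_s = 0.0
        settings = comps.settings
        times, bottoms, devs = [0.0], [point_sample(state, name, obs["bottom_um"], obs["window_um"])], []
        mean0 = float(state.c[name].mean())
        devs.append(float(np.max(np.abs(state.c[name] / mean0 - 1.0))))
        t_end = duration_h * 3600.0
        dt = settings.dt_init_s
        t_uniform = 0.0 if devs[0] < tol else float("inf")
        while state.time_s < t_end - 1e-9:
            dt = min(dt, t_end - state.time_s)
            state = sys.step(state, dt)
            mean = float(state.c[name].mean())
            dev = float(np.max(np.abs(state.c[name] / mean - 1.0)))
            times.append(state.time_s / 3600.0)
            bottoms.append(point_sample(state, name, obs["bottom_um"], obs["window_um"]))
            devs.append(dev)
            if dev < tol and not np.isfinite(t_uniform):
                t_uniform = state.time_s / 3600.0
                break
            dt = min(dt * settings.dt_growth, settings.dt_max_s)
        return t_uniform, np.asarray(times), np.asarray(bottoms), np.asarray(devs), comps

    t_uniform, times, bottoms, devs, comps = relax(T_iso, cfg["duration_h"])
    # short comparison run at the hot-plate temperature: diffusion is faster
    T_hot = cfg["thermal"]["T_hot_C"]
    _, t40, b40, _, _ = relax(T_hot, 6.0)
    decay_6h_cold = float(np.interp(6.0, times, bottoms) / bottoms[0]) if bottoms[0] > 0 else np.nan
    decay_6h_hot = float(b40[-1] / b40[0]) if b40[0] > 0 else np.nan

    import pandas as pd

    frame = pd.DataFrame({"time_h": times, "bottom_uM": bottoms, "max_rel_deviation": devs})
    metrics = {
        "isothermal_T_C": T_iso,
        "time_to_uniform_h": t_uniform,
        "uniformity_tol": tol,
        "D_um2_s_isothermal": comps.species[name].D_um2_s,
        "bottom_fraction_left_6h_cold": decay_6h_cold,
        "bottom_fraction_left_6h_hot": decay_6h_hot,
    }
    return ScenarioReport(
        "isothermal_relaxation",
        metrics,
        config_hash(cfg),
        cfg.get("seed"),
        _solver_info(comps),
        series={"relaxation": frame},
    )


RUNNERS = {
    "closed_accumulation": run_closed_accumulation,
    "retention": run_retention,
    "feeding_activation": run_feeding_activation,
    "feed_waste": run_feed_waste,
    "thickness_scan": run_thickness_scan,
    "isothermal_relaxation": run_isothermal_relaxation,
}


def run_scenario(cfg: dict) -> ScenarioReport:
    name = cfg.get("scenario")
    if name not in RUNNERS:
        raise ValueError(f"unknown scenario {name!r}")
    return RUNNERS[name](cfg)
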