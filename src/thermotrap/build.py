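"""Turn a scenario configuration dict into solver-ready components.

The builder resolves derived quantities once per build: the chamber depth
from the fill volume, fluid properties at the mean temperature, species
diffusion coefficients from Stokes-Einstein radii (divided by the solution
viscosity factor), the thermophoretic drift of each species and, for species
whose Soret coefficient is declared ``"calibrated"``, the value that pins
the closed-trap steady bottom/top point ratio to the configured fold target
(memoized per configuration).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import water
from .trap_model import (
    ChamberGeometry,
    FlowField,
    FluidProps,
    Species,
    ThermalField,
    convection_field,
    drift_field,
    make_geometry,
    thermal_field,
)
from .transport import (
    FlowBC,
    SolverSettings,
    TransportOperator,
    TransportSystem,
    assemble_operator,
)

_CALIBRATION_CACHE: dict[tuple, float] = {}


@dataclass
class Components:
    """Everything needed to run one scenario configuration."""

    cfg: dict
    geometry: ChamberGeometry
    thermal: ThermalField
    fluid: FluidProps
    flow_field: FlowField
    species: dict[str, Species]
    drift_um_s: dict[str, float]
    operators: dict[str, TransportOperator]
    bc: dict[str, FlowBC | None]
    settings: SolverSettings

    def system(self, reaction=None, expression=None) -> TransportSystem:
        return TransportSystem(self.geometry, self.operators, reaction, expression)

    @property
    def species_list(self) -> list[Species]:
        return list(self.species.values())


def set_species_param(cfg: dict, name: str, **params) -> dict:
    """Copy of the config with parameters of one species replaced."""
    out = copy.deepcopy(cfg)
    for entry in out["species"]:
        if entry["name"] == name:
            entry.update(params)
            # an explicit D supersedes a Stokes-Einstein radius
            if "D_um2_s" in params:
                entry.pop("stokes_radius_nm", None)
            return out
    raise KeyError(f"species {name!r} not in config")


def _resolve_D(entry: dict, T_C: float, viscosity_factor: float, T_ref_C: float) -> float:
    if "D_um2_s" in entry:
        D = float(entry["D_um2_s"])
        if T_C != T_ref_C:
            D = water.rescale_D(D, T_ref_C, T_C)
        return D
    if "stokes_radius_nm" in entry:
        return water.stokes_einstein_D_um2_s(entry["stokes_radius_nm"], T_C, viscosity_factor)
    raise ValueError(f"species {entry.get('name')!r} has neither D_um2_s nor stokes_radius_nm")


def _resolve_S_T(entry: dict, cfg: dict) -> float:
    raw = entry["S_T_per_K"]
    if raw != "calibrated":
        return float(raw)
    target = float(entry.get("relative_fold_target", 25.0))
    key = _calibration_key(cfg, entry, target)
    if key not in _CALIBRATION_CACHE:
        from .calibration import soret_from_relative_accumulation

        _CALIBRATION_CACHE[key] = soret_from_relative_accumulation(
            target, cfg, species_entry=entry
        )
    return _CALIBRATION_CACHE[key]


def _calibration_key(cfg: dict, entry: dict, target: float) -> tuple:
    geo = cfg["geometry"]
    th = cfg["thermal"]
    obs = cfg.get("observables", {})
    return (
        geo["gap_um"],
        geo["height_um"],
        geo.get("fill_volume_ul"),
        geo["n_x"],
        geo["n_z"],
        th["T_cold_C"],
        th["T_hot_C"],
        cfg["fluid"]["viscosity_factor"],
        entry.get("stokes_radius_nm"),
        entry.get("D_um2_s"),
        obs.get("bottom_um", 500.0),
        obs.get("top_um"),
        obs.get("window_um", 500.0),
        target,
    )


def default_channel_volume_ul(geometry: ChamberGeometry, radius_um: float = 500.0) -> float:
    """Volume of a 1 mm diameter channel spanning the chamber depth."""
    return float(np.pi * radius_um**2 * geometry.depth_um / 1e9)


def build(cfg: dict, isothermal_T_C: float | None = None) -> Components:
    """Build geometry, fields, species and transport operators from a config.

    ``isothermal_T_C`` rebuilds the scenario with both plates at the given
    temperature (gradient off): convection and thermophoretic drift vanish
    and every diffusion coefficient is re-evaluated at that temperature via
    Stokes-Einstein T/eta scaling.
    """
    geo = cfg["geometry"]
    geometry = make_geometry(
        gap_um=geo["gap_um"],
        height_um=geo["height_um"],
        fill_volume_ul=geo.get("fill_volume_ul"),
        depth_um=geo.get("depth_um"),
        n_x=geo["n_x"],
        n_z=geo["n_z"],
        orientation=geo.get("orientation", "vertical"),
    )
    th = cfg["thermal"]
    T_ref = 0.5 * (th["T_cold_C"] + th["T_hot_C"])
    if isothermal_T_C is None:
        thermal = thermal_field(geometry, th["T_cold_C"], th["T_hot_C"])
    else:
        thermal = thermal_field(geometry, isothermal_T_C, isothermal_T_C)
    f_visc = cfg["fluid"]["viscosity_factor"]
    fluid = FluidProps.from_water(thermal.T_mean_C, f_visc)
    flow = convection_field(geometry, thermal, fluid)

    flow_cfg = cfg.get("flow", {}) or {}
    flow_enabled = bool(flow_cfg.get("enabled", False))
    channel_vol = flow_cfg.get("channel_volume_ul") or default_channel_volume_ul(geometry)
    feed_map = flow_cfg.get("feed_uM", {}) or {}

    species: dict[str, Species] = {}
    drift: dict[str, float] = {}
    operators: dict[str, TransportOperator] = {}
    bcs: dict[str, FlowBC | None] = {}
    scheme = cfg.get("solver", {}).get("scheme", "sg")
    for entry in cfg["species"]:
        name = entry["name"]
        D = _resolve_D(entry, thermal.T_mean_C, f_visc, T_ref)
        S_T = _resolve_S_T(entry, cfg)
        sp = Species(name, D, S_T, c0_uM=float(entry.get("c0_uM", 0.0)), role=entry.get("role", "protein"))
        species[name] = sp
        drift[name] = drift_field(sp, thermal)
        bc = None
        if flow_enabled:
            bc = FlowBC(
                flow_rate_ul_h=float(flow_cfg.get("flow_rate_ul_h", 11.0)),
                feed_uM=float(feed_map.get(name, 0.0)),
                channel_volume_ul=channel_vol,
                channel_radius_um=float(flow_cfg.get("channel_radius_um", 500.0)),
                enabled=True,
                exchange=bool(flow_cfg.get("exchange", True)),
            )
        bcs[name] = bc
        operators[name] = assemble_operator(geometry, flow, drift[name], sp, bc=bc, scheme=scheme)

    sv = cfg.get("solver", {})
    settings = SolverSettings(
        dt_init_s=sv.get("dt_init_s", 10.0),
        dt_max_s=sv.get("dt_max_s", 1800.0),
        dt_growth=sv.get("dt_growth", 1.2),
        scheme=scheme,
        steady_tol_per_h=sv.get("steady_tol_per_h", 1e-6),
    )
    return Components(cfg, geometry, thermal, fluid, flow, species, drift, operators, bcs, settings)


def clear_calibration_cache() -> None:
    _CALIBRATION_CACHE.clear()
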