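"""Estimate transport parameters from position-resolved fluorescence series.

The inverse problem mirrors how transport coefficients are obtained in
thermal-trap experiments: position-resolved fluorescence kinetics are fitted
by the forward transport model with the Soret coefficient (and optionally
the diffusion coefficient and the solution viscosity factor) free.
Fluorescence is a relative signal, so every observation position carries a
multiplicative nuisance scale that is profiled out in closed form inside the
residual.

``soret_from_relative_accumulation`` is the complementary, observable-pinned
route: it root-finds the Soret coefficient at which the closed-trap steady
state reproduces a stated bottom/top fold -- the mechanism used to anchor
the reporter protein's S_T to the observed 25-fold relative accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as opt

from .build import build as build_scenario, set_species_param
from .observables import relative_accumulation
from .transport import initial_state, steady_state

_DEFAULT_BOUNDS = {"S_T": (1e-5, 0.5), "D": (1.0, 5000.0), "f_visc": (1.0, 3.0)}


@dataclass
class ObservedSeries:
    """Long-form position-resolved observations (arbitrary fluorescence units)."""

    time_h: np.ndarray
    position_mm: np.ndarray
    value: np.ndarray
    noise_cv: float | None = None

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if not (len(self.time_h) == len(self.position_mm) == len(self.value)):
            raise ValueError("time, position and value must have equal length")

    @property
    def positions(self) -> np.ndarray:
        return np.unique(self.position_mm)

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.time_h)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time_h, "position_mm": self.position_mm, "value": self.value}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, noise_cv: float | None = None) -> "ObservedSeries":
        return cls(
            df["time_h"].to_numpy(), df["position_mm"].to_numpy(), df["value"].to_numpy(), noise_cv
        )


@dataclass
class CalibrationResult:
    """Fitted parameters with bounds, curvature-based half-widths and diagnostics."""

    params: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    residual_norm: float
    half_widths: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_starts: int = 1
    message: str = ""


def _apply_params(cfg: dict, species: str, params: dict[str, float]) -> dict:
    out = cfg
    updates = {}
    if "S_T" in params:
        updates["S_T_per_K"] = float(params["S_T"])
    if "D" in params:
        updates["D_um2_s"] = float(params["D"])
    if updates:
        out = set_species_param(out, species, **updates)
    if "f_visc" in params:
        import copy

        out = copy.deepcopy(out)
        out["fluid"]["viscosity_factor"] = float(params["f_visc"])
    return out


def simulate_observables(
    params: dict[str, float],
    cfg: dict,
    positions_mm: np.ndarray,
    times_h: np.ndarray,
    species: str = "sfGFP",
) -> ObservedSeries:
    """Forward model evaluated at the observation coordinates (deterministic).

    Runs the closed-trap transient from the uniform initial state and samples
    the gap-averaged concentration at each position/time with the scenario's
    observation window.
    """
    cfg2 = _apply_params(cfg, species, params)
    comps = build_scenario(cfg2)
    window = cfg.get("observables", {}).get("window_um", 500.0)
    positions_um = np.asarray(positions_mm, dtype=float) * 1000.0
    times_h = np.asarray(times_h, dtype=float)
    sys = comps.system()
    state = initial_state(comps.geometry, comps.species_list, bc=comps.bc[species])
    series, _ = sys.run(
        state,
        float(times_h.max()) * 3600.0,
        comps.settings,
        record_positions_um=tuple(positions_um),
        window_um=window,
    )
    t_out, p_out, v_out = [], [], []
    for pos_mm, pos_um in zip(positions_mm, positions_um):
        for t in times_h:
            t_out.append(t)
            p_out.append(pos_mm)
            v_out.append(series.value_at(species, pos_um, t))
    return ObservedSeries(np.array(t_out), np.array(p_out), np.array(v_out))


def _profiled_residuals(y: ObservedSeries, model: ObservedSeries) -> np.ndarray:
    """Weighted residuals after profiling out one multiplicative scale per position.

    Fluorescence errors are predominantly multiplicative with an additive
    floor, so residuals are weighted by 1/(model + 0.1 * max(model)) -- a
    mixed error model that follows the relative noise over the signal's
    dynamic range without letting near-zero (floor-dominated) samples take
    over.  The per-position scale is the weighted least-squares optimum.
    """
    resid = np.empty_like(y.value)
    eps = 0.1 * float(np.max(model.value))
    for pos in y.positions:
        sel = y.position_mm == pos
        m = np.interp(y.time_h[sel], model.times, _model_series(model, pos))
        w = 1.0 / (m + eps) if eps > 0 else np.ones_like(m)
        denom = float((m * m * w * w).sum())
        scale = float((y.value[sel] * m * w * w).sum()) / denom if denom > 0 else 0.0
        resid[sel] = (y.value[sel] - scale * m) * w
    return resid


def _model_series(model: ObservedSeries, pos: float) -> np.ndarray:
    sel = model.position_mm == pos
    order = np.argsort(model.time_h[sel])
    return model.value[sel][order]


def fit_soret(
    observed: ObservedSeries,
    cfg: dict,
    free_params: tuple[str, ...] = ("S_T",),
    species: str = "sfGFP",
    bounds: dict[str, tuple[float, float]] | None = None,
    x0: dict[str, float] | None = None,
    n_starts: int = 3,
) -> CalibrationResult:
    """Weighted least squares over the forward model, log-parametrized.

    Uses deterministic multi-starts (geometric perturbations of the initial
    guess) and reports finite-difference curvature half-widths.  A
    configuration that cannot constrain the parameters (a single position at
    a single time, or jointly free D and S_T against a single steady profile)
    is rejected as non-identifiable.
    """
    free = tuple(free_params)
    unknown = set(free) - set(_DEFAULT_BOUNDS)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    n_pos, n_t = len(observed.positions), len(observed.times)
    if n_pos < 2:
        raise ValueError("non-identifiable: need observations at >= 2 positions")
    if n_t < 2 and {"D", "S_T"} <= set(free):
        raise ValueError(
            "non-identifiable: a single steady profile constrains only the ratio of D and S_T"
        )
    bnds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    defaults = {"S_T": 1e-2, "D": 100.0, "f_visc": 1.3}
    start = {**defaults, **(x0 or {})}

    times_h = observed.times
    positions_mm = observed.positions

    def residual(theta: np.ndarray) -> np.ndarray:
        params = {p: np.exp(t) for p, t in zip(free, theta)}
        model = simulate_observables(params, cfg, positions_mm, times_h, species)
        return _profiled_residuals(observed, model)

    lb = np.log([bnds[p][0] for p in free])
    ub = np.log([bnds[p][1] for p in free])
    starts = []
    factors = [1.0, 0.4, 2.5]
    for k in range(max(1, n_starts)):
        f = factors[k % len(factors)]
        starts.append(np.clip(np.log([start[p] * f for p in free]), lb, ub))

    best = None
    for theta0 in starts:
        res = opt.least_squares(residual, theta0, bounds=(lb, ub), xtol=1e-10, ftol=1e-10)
        if best is None or res.cost < best.cost:
            best = res

    values = {p: float(np.exp(t)) for p, t in zip(free, best.x)}
    # curvature-based half-widths from the Jacobian in log-space
    half = {}
    try:
        J = best.jac
        dof = max(len(best.fun) - len(free), 1)
        sigma2 = 2.0 * best.cost / dof
        cov = sigma2 * np.linalg.inv(J.T @ J)
        for i, p in enumerate(free):
            half[p] = float(values[p] * 1.96 * np.sqrt(max(cov[i, i], 0.0)))
    except np.linalg.LinAlgError:
        half = {p: float("nan") for p in free}
    return CalibrationResult(
        params=values,
        bounds={p: bnds[p] for p in free},
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        half_widths=half,
        converged=bool(best.status > 0),
        n_starts=len(starts),
        message=str(best.message),
    )


def soret_from_relative_accumulation(
    target_ratio: float,
    cfg: dict,
    species: str = "sfGFP",
    species_entry: dict | None = None,
    bounds: tuple[float, float] = (1e-5, 0.3),
) -> float:
    """Soret coefficient whose closed-trap steady state shows the target BOT/TOP.

    Bracketed, monotone root search on the stationary forward model with the
    scenario's point-sampling convention.  ``target_ratio = 1`` maps to
    ``S_T = 0`` (no thermophoresis, uniform steady state).
    """
    if target_ratio < 1:
        raise ValueError("target ratio must be >= 1")
    if target_ratio == 1:
        return 0.0
    if species_entry is not None:
        species = species_entry["name"]
    obs = cfg.get("observables", {})
    bottom = obs.get("bottom_um", 500.0)
    top = obs.get("top_um")
    window = obs.get("window_um", 500.0)

    import copy

    base = copy.deepcopy(cfg)
    base["flow"] = {"enabled": False}
    base.pop("reaction", None)
    base.pop("expression", None)
    # only the target species is needed for the stationary solve
    for entry in base["species"]:
        if entry["name"] == species:
            entry = copy.deepcopy(entry)
            entry["c0_uM"] = max(float(entry.get("c0_uM", 1.0)), 1.0)
            base["species"] = [entry]
            break
    else:
        raise KeyError(f"species {species!r} not in config")

    def ratio(S_T: float) -> float:
        cfg2 = set_species_param(base, species, S_T_per_K=float(S_T))
        comps = build_scenario(cfg2)
        op = comps.operators[species]
        init = initial_state(comps.geometry, comps.species_list)
        st = steady_state(op, init=init)
        from .transport import point_sample

        bot = point_sample(st, species, bottom, window)
        top_v = point_sample(st, species, top if top is not None else comps.geometry.height_um - bottom, window)
        if top_v <= 0:  # profile so steep the top signal underflows
            return 1e12
        return min(bot / top_v, 1e12)

    lo, hi = bounds
    f_lo = ratio(lo) - target_ratio
    if f_lo > 0:
        raise ValueError("target ratio below the reachable range")
    f_hi = ratio(hi) - target_ratio
    grow = 0
    while f_hi < 0:
        hi *= 2.0
        grow += 1
        if grow > 4:
            raise ValueError("target ratio unreachable within the Soret bounds")
        f_hi = ratio(hi) - target_ratio
    return float(opt.brentq(lambda s: ratio(s) - target_ratio, lo, hi, rtol=1e-5))
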