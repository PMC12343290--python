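"""Synthetic observation datasets with known ground truth.

Emulates position-resolved fluorescence kinetics of the kind recorded in
thermal-trap experiments: the forward transport model evaluated at the
sample positions/times, degraded by multiplicative log-normal noise (the
dominant error mode of relative fluorescence measurements) plus an additive
Gaussian floor (camera/background).  The generating parameters are always
written to a ground-truth sidecar so parameter-recovery studies never have
to reach through the fitting path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .build import build as build_scenario
from .calibration import ObservedSeries, simulate_observables
from .observables import freeze_fractions
from .transport import initial_state


@dataclass
class SyntheticSpec:
    """Ground-truth parameters, sampling design and noise model."""

    cfg: dict
    true_params: dict[str, float]  # subset of {S_T, D, f_visc}
    species: str = "sfGFP"
    positions_mm: tuple[float, ...] = (0.5, 34.5)
    times_h: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 16.0, 24.0)
    noise_cv: float = 0.05
    additive_floor_frac: float = 0.01  # sd of the additive term, x initial signal
    seed: int | None = None

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.noise_cv > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for noisy output")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with the requested CV."""
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n)


def generate_fluorescence_series(spec: SyntheticSpec) -> tuple[ObservedSeries, dict]:
    """Noisy position-resolved series plus the ground-truth sidecar dict.

    Noise-free generation (CV = 0, zero floor) is the identity on the forward
    model; for a fixed seed the output is bit-reproducible.
    """
    clean = simulate_observables(
        spec.true_params,
        spec.cfg,
        np.asarray(spec.positions_mm),
        np.asarray(spec.times_h),
        species=spec.species,
    )
    values = clean.value.copy()
    if spec.noise_cv > 0 or spec.additive_floor_frac > 0:
        if spec.seed is None:
            raise ValueError("a seed is mandatory for noisy output")
        rng = np.random.default_rng(spec.seed)
        if spec.noise_cv > 0:
            values = values * _lognormal_factors(rng, spec.noise_cv, len(values))
        if spec.additive_floor_frac > 0:
            floor_sd = spec.additive_floor_frac * float(np.mean(np.abs(clean.value[clean.time_h == clean.time_h.min()])))
            values = values + rng.normal(0.0, floor_sd, size=len(values))
    observed = ObservedSeries(clean.time_h, clean.position_mm, values, noise_cv=spec.noise_cv)
    sidecar = {
        "true_params": dict(spec.true_params),
        "species": spec.species,
        "noise_cv": spec.noise_cv,
        "additive_floor_frac": spec.additive_floor_frac,
        "seed": spec.seed,
        "positions_mm": list(spec.positions_mm),
        "times_h": list(spec.times_h),
    }
    return observed, sidecar


def generate_fraction_measurements(
    spec: SyntheticSpec, duration_h: float = 16.0
) -> tuple[dict, dict]:
    """Thirds-fraction means (with noise) for a closed-trap incubation.

    Returns ``({species: {TOP, MID, BOT, relative_fold}}, sidecar)``; used to
    exercise the freeze-extraction fold-statistic code paths end to end.
    """
    from .calibration import _apply_params

    cfg2 = _apply_params(spec.cfg, spec.species, spec.true_params)
    comps = build_scenario(cfg2)
    sys = comps.system()
    state = initial_state(comps.geometry, comps.species_list)
    _, final = sys.run(state, duration_h * 3600.0, comps.settings)
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    out = {}
    truth = {}
    for name in comps.species:
        rep = freeze_fractions(final, name)
        vals = np.array([rep.top_uM, rep.mid_uM, rep.bot_uM])
        truth[name] = {"TOP": rep.top_uM, "MID": rep.mid_uM, "BOT": rep.bot_uM}
        if spec.noise_cv > 0:
            if rng is None:
                raise ValueError("a seed is mandatory for noisy output")
            vals = vals * _lognormal_factors(rng, spec.noise_cv, 3)
        out[name] = {
            "TOP": float(vals[0]),
            "MID": float(vals[1]),
            "BOT": float(vals[2]),
            "relative_fold": float(vals[2] / vals[0]) if vals[0] > 0 else float("inf"),
        }
    sidecar = {
        "true_params": dict(spec.true_params),
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
        "duration_h": duration_h,
        "fractions_true": truth,
    }
    return out, sidecar


def write_dataset(observed: ObservedSeries, sidecar: dict, csv_path, sidecar_path) -> None:
    """CSV observations plus JSON ground-truth sidecar."""
    observed.to_dataframe().to_csv(csv_path, index=False)
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
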