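"""Measurement statistics of the thermal trap experiments.

Two sampling conventions coexist in this kind of experiment and both are
implemented explicitly:

* point sampling -- gap-averaged fluorescence in a small vertical window,
  the real-time imaging convention; relative accumulation is the ratio of
  the bottom to the top point sample (BOT/TOP), absolute accumulation the
  ratio of the final to the initial bottom sample (BOT_final/BOT_start);
* thirds fractions -- the destructive "freeze extraction" convention: the
  chamber content is sectioned into exact top/middle/bottom thirds of the
  height and each third is averaged.  Averaging over a third attenuates the
  extremes of an exponential profile, so thirds-based fold values are always
  smaller than point-based ones.

Retention under top-channel flow is the trap-region amount (channel
excluded) relative to its initial value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import TransportState, TrapTimeSeries, point_sample, total_mass

sample_point = point_sample  # re-export under the statistics namespace


@dataclass(frozen=True)
class FractionReport:
    """Mean concentrations of the exact height thirds plus the fold statistics."""

    species: str
    top_uM: float
    mid_uM: float
    bot_uM: float
    boundaries_mm: tuple[float, float]
    relative_accumulation: float  # BOT/TOP, thirds convention
    trap_mean_uM: float


def _third_weights(n_z: int) -> np.ndarray:
    """(3, n_z) overlap weights of each exact height third with the z cells.

    Rows sum to n_z/3 regardless of divisibility, so the thirds partition
    the height exactly and their mean recovers the trap mean identically.
    """
    edges = np.arange(n_z + 1, dtype=float)  # cell edges in units of dz
    weights = np.zeros((3, n_z))
    for k in range(3):
        lo, hi = k * n_z / 3.0, (k + 1) * n_z / 3.0
        overlap = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
        weights[k] = np.clip(overlap, 0.0, None)
    return weights


def freeze_fractions(state: TransportState, species: str) -> FractionReport:
    """Volume-weighted means over exact height thirds (freeze-extraction emulation)."""
    geom = state.geometry
    prof = state.gap_profile(species)
    w = _third_weights(geom.n_z)
    means = (w @ prof) / w.sum(axis=1)
    bot, mid, top = means  # k=0 is the bottom third (z from 0)
    h_mm = geom.height_um / 1000.0
    rel = bot / top if top > 0 else np.inf
    return FractionReport(
        species=species,
        top_uM=float(top),
        mid_uM=float(mid),
        bot_uM=float(bot),
        boundaries_mm=(h_mm / 3.0, 2.0 * h_mm / 3.0),
        relative_accumulation=float(rel),
        trap_mean_uM=float(prof.mean()),
    )


def relative_accumulation(
    state: TransportState,
    species: str,
    convention: str = "point",
    bottom_um: float = 500.0,
    top_um: float | None = None,
    window_um: float = 500.0,
) -> float:
    """BOT/TOP fold, by point sampling (imaging) or thirds (freeze extraction)."""
    if convention == "thirds":
        report = freeze_fractions(state, species)
        if report.top_uM <= 0:
            raise ValueError("top fraction signal is not positive")
        return report.relative_accumulation
    if convention != "point":
        raise ValueError(f"unknown convention {convention!r}")
    if top_um is None:
        top_um = state.geometry.height_um - bottom_um
    bot = point_sample(state, species, bottom_um, window_um)
    top = point_sample(state, species, top_um, window_um)
    if top <= 0:
        raise ValueError("top point signal is not positive")
    return bot / top


def absolute_accumulation(
    series: TrapTimeSeries, species: str, position_um: float = 500.0
) -> float:
    """BOT_final / BOT_start: net enrichment at a position over the run."""
    values = series.sample_series(species, position_um)
    if values[0] <= 0:
        raise ValueError("start value is not positive")
    return float(values[-1] / values[0])


def retention_fraction(series: TrapTimeSeries, species: str) -> np.ndarray:
    """Trap-region amount over its initial value, per recorded time."""
    mass = series.trap_mass_pmol[species]
    if mass[0] <= 0:
        raise ValueError("zero initial amount in the trap")
    return mass / mass[0]


def retention_at(series: TrapTimeSeries, species: str, time_h: float) -> float:
    frac = retention_fraction(series, species)
    return float(np.interp(time_h, series.times_h, frac))


def time_to_uniform(
    series_states: list[TransportState], species: str, tol: float = 0.05
) -> float:
    """First recorded time (h) at which max |c/mean - 1| < tol over the trap."""
    for st in series_states:
        prof = st.gap_profile(species)
        mean = prof.mean()
        if mean <= 0:
            continue
        if np.max(np.abs(st.c[species] / mean - 1.0)) < tol:
            return st.time_s / 3600.0
    return np.inf


__all__ = [
    "FractionReport",
    "sample_point",
    "point_sample",
    "freeze_fractions",
    "relative_accumulation",
    "absolute_accumulation",
    "retention_fraction",
    "retention_at",
    "time_to_uniform",
    "total_mass",
]
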