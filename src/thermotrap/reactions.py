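"""Local reaction kinetics coupled to transport by operator splitting.

Two reaction models are provided:

* Michaelis-Menten conversion of a fed substrate (ATP) into orthophosphate
  waste, spatially uniform enzyme activity over the trap -- the feed/waste
  scenario.  The split step uses the backward-Euler update of the MM rate
  law, which reduces to a quadratic with a closed-form positive root, so the
  update is unconditionally stable and positivity preserving at any dt.
* A Hill-type expression activation used only for the qualitative feeding
  scenario: synthesis of the reporter protein switches on where the fed
  limiting component exceeds a threshold, optionally scaled by the local
  abundance of a transported "machinery" tracer standing in for the
  translation apparatus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import TransportState


@dataclass(frozen=True)
class ReactionSpec:
    """Michaelis-Menten substrate -> product conversion, uniform over the trap."""

    substrate: str = "ATP"
    product: str = "phosphate"
    vmax_uM_s: float = 1e-3
    km_uM: float = 100.0
    stoichiometry: float = 1.0

    def __post_init__(self):
        if self.vmax_uM_s < 0:
            raise ValueError("V_max must be >= 0")
        if self.km_uM <= 0:
            raise ValueError("K_M must be positive")
        if self.stoichiometry <= 0:
            raise ValueError("stoichiometry must be positive")


def mm_rate(c_substrate: np.ndarray | float, spec: ReactionSpec) -> np.ndarray | float:
    """Michaelis-Menten rate ``V_max c / (K_M + c)``, elementwise (uM/s)."""
    c = np.asarray(c_substrate, dtype=float)
    rate = spec.vmax_uM_s * c / (spec.km_uM + c)
    return rate if rate.shape else float(rate)


def _mm_implicit_update(c0: np.ndarray, spec: ReactionSpec, dt: float) -> np.ndarray:
    """Backward-Euler MM update: positive root of c^2 + (K-c0+Vdt)c - c0 K = 0."""
    half_b = 0.5 * (spec.km_uM - c0 + spec.vmax_uM_s * dt)
    c_new = -half_b + np.sqrt(half_b**2 + c0 * spec.km_uM)
    return np.maximum(c_new, 0.0)


def react_step(
    state: TransportState, spec: ReactionSpec, dt: float, in_place: bool = False
) -> TransportState:
    """Operator-split reaction update over the trap cells.

    The substrate decrease equals the stoichiometry-weighted product increase
    cell by cell, so the split step is exactly mass balanced.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    for name in (spec.substrate, spec.product):
        if name not in state.c:
            raise KeyError(f"species {name!r} not present in the state")
    new = state if in_place else state.copy()
    if dt == 0 or spec.vmax_uM_s == 0:
        return new
    c0 = new.c[spec.substrate]
    c1 = _mm_implicit_update(c0, spec, dt)
    new.c[spec.substrate] = c1
    new.c[spec.product] = new.c[spec.product] + spec.stoichiometry * (c0 - c1)
    return new


@dataclass(frozen=True)
class ExpressionSpec:
    """Hill-type activation of reporter synthesis by an accumulated feed component."""

    limiting: str = "feed"
    product: str = "sfGFP"
    threshold_uM: float = 0.3
    hill: float = 4.0
    max_rate_uM_s: float = 1e-4
    machinery: str | None = None  # optional transported tracer scaling the rate
    machinery_ref_uM: float = 1.0
    machinery_yield: float | None = None  # uM product per uM machinery (finite capacity)
    enabled: bool = False

    def __post_init__(self):
        if self.threshold_uM <= 0 or self.hill <= 0 or self.max_rate_uM_s < 0:
            raise ValueError("expression parameters must be positive")
        if self.machinery_yield is not None and self.machinery_yield <= 0:
            raise ValueError("machinery yield must be positive")


def expression_rate(
    local_concentrations: dict[str, np.ndarray], spec: ExpressionSpec
) -> np.ndarray:
    """Synthesis rate field (uM/s): Hill switch in the limiting component."""
    if not spec.enabled:
        raise ValueError("expression model is disabled")
    c = np.maximum(np.asarray(local_concentrations[spec.limiting], dtype=float), 0.0)
    h = c**spec.hill
    rate = spec.max_rate_uM_s * h / (spec.threshold_uM**spec.hill + h)
    if spec.machinery is not None:
        rate = rate * np.maximum(local_concentrations[spec.machinery], 0.0) / spec.machinery_ref_uM
    return rate


def expression_step(
    state: TransportState, spec: ExpressionSpec, dt: float, in_place: bool = False
) -> TransportState:
    """Explicit split step adding synthesized product (rates are slow vs transport).

    With a finite ``machinery_yield`` the machinery tracer is consumed in
    proportion to synthesis (batch expression capacity), so locally active
    regions exhaust over time.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    new = state if in_place else state.copy()
    if dt == 0:
        return new
    rate = expression_rate(new.c, spec)
    made = dt * rate
    if spec.machinery is not None and spec.machinery_yield is not None:
        used = made / spec.machinery_yield
        avail = np.maximum(new.c[spec.machinery], 0.0)
        # cap the step so machinery cannot be driven negative
        over = used > avail
        scale = np.ones_like(avail)
        scale[over] = avail[over] / used[over]
        made = made * scale
        new.c[spec.machinery] = avail - made / spec.machinery_yield
    new.c[spec.product] = new.c[spec.product] + made
    return new
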