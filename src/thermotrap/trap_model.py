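"""Geometry, temperature, convection and thermophoretic drift of a thermal trap.

The trap is a thin vertical chamber: a gap of width ``w`` (default 170 um)
between a cold and a hot sapphire plate, a height ``H`` (default 35 mm) and a
depth chosen so the chamber holds the filled sample volume (60 ul by
default).  The model is two dimensional (gap x height); the depth enters only
when converting concentrations to absolute amounts and flow rates.

Coordinate convention: ``x`` runs from the cold wall (x=0) to the hot wall
(x=w); ``z`` runs from the chamber bottom (z=0) upwards.  All grids are
cell-centered and uniform.

The temperature field is linear across the gap and uniform along the height
(the sapphire plates impose near-uniform wall temperatures and the aspect
ratio H/w ~ 200 makes end effects negligible).  The buoyancy-driven
convection between differentially heated walls is the fully developed
Boussinesq slot profile

    u(x~) = -(g * beta * dT * w^2 / (12 nu)) * x~ (1 - x~)(1 - 2 x~)

with ``x~ = x/w`` and ``u`` positive upward, i.e. the fluid sinks along the
denser cold wall and rises along the hot wall.  Thermophoresis adds a
cross-gap drift ``v_T = -D * S_T * grad T`` that pushes solutes with positive
Soret coefficient toward the cold wall, where the downward convection carries
them to the chamber bottom -- the thermogravitational accumulation mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import water

UL_TO_UM3 = 1e9  # 1 ul = 1e9 um^3


@dataclass(frozen=True)
class ChamberGeometry:
    """Cross-section and grid of the trap.

    Lengths in um.  ``n_x`` cells across the gap, ``n_z`` along the height.
    """

    gap_um: float
    height_um: float
    depth_um: float
    n_x: int = 34
    n_z: int = 350
    orientation: str = "vertical"

    def __post_init__(self):
        if self.gap_um <= 0 or self.height_um <= 0 or self.depth_um <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.n_x < 8:
            raise ValueError("need at least 8 cells across the gap")
        if self.n_z < 1 or self.n_x < 1:
            raise ValueError("grid sizes must be positive")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def dx(self) -> float:
        return self.gap_um / self.n_x

    @property
    def dz(self) -> float:
        return self.height_um / self.n_z

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_x) + 0.5) * self.dx

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.n_z) + 0.5) * self.dz

    @property
    def cell_volume_um3(self) -> float:
        return self.dx * self.dz * self.depth_um

    @property
    def cell_volume_ul(self) -> float:
        return self.cell_volume_um3 / UL_TO_UM3

    @property
    def trap_volume_ul(self) -> float:
        return self.gap_um * self.height_um * self.depth_um / UL_TO_UM3

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_z


def make_geometry(
    gap_um: float = 170.0,
    height_um: float = 35_000.0,
    fill_volume_ul: float | None = 60.0,
    depth_um: float | None = None,
    n_x: int = 34,
    n_z: int = 350,
    orientation: str = "vertical",
) -> ChamberGeometry:
    """Build the chamber grid; the depth is derived from the fill volume when not given."""
    if gap_um <= 0 or height_um <= 0:
        raise ValueError("chamber dimensions must be positive")
    if depth_um is None:
        if fill_volume_ul is None or fill_volume_ul <= 0:
            raise ValueError("either a positive fill volume or an explicit depth is required")
        depth_um = fill_volume_ul * UL_TO_UM3 / (gap_um * height_um)
    return ChamberGeometry(gap_um, height_um, depth_um, n_x=n_x, n_z=n_z, orientation=orientation)


@dataclass(frozen=True)
class FluidProps:
    """Bulk fluid properties evaluated at the mean chamber temperature."""

    kinematic_viscosity_um2_s: float
    thermal_expansion_per_K: float
    density_kg_m3: float
    gravity_um_s2: float = water.GRAVITY_UM_S2
    viscosity_factor: float = 1.0

    def __post_init__(self):
        if min(self.kinematic_viscosity_um2_s, self.thermal_expansion_per_K,
               self.density_kg_m3, self.gravity_um_s2) <= 0:
            raise ValueError("fluid properties must be positive")
        if self.viscosity_factor < 1.0:
            raise ValueError("viscosity factor applies on top of water; must be >= 1")

    @classmethod
    def from_water(cls, T_mean_C: float, viscosity_factor: float = 1.0) -> "FluidProps":
        return cls(
            kinematic_viscosity_um2_s=water.kinematic_viscosity_um2_s(T_mean_C, viscosity_factor),
            thermal_expansion_per_K=water.thermal_expansion_per_K(T_mean_C),
            density_kg_m3=water.density_kg_m3(T_mean_C),
            viscosity_factor=viscosity_factor,
        )


@dataclass(frozen=True)
class ThermalField:
    """Linear cross-gap temperature field, uniform along the height."""

    T_cold_C: float
    T_hot_C: float
    T_x: np.ndarray  # degC at the x cell centers
    grad_K_per_um: float  # dT/dx along +x (cold -> hot), >= 0

    @property
    def delta_T(self) -> float:
        return self.T_hot_C - self.T_cold_C

    @property
    def T_mean_C(self) -> float:
        return 0.5 * (self.T_cold_C + self.T_hot_C)


def thermal_field(geometry: ChamberGeometry, T_cold_C: float, T_hot_C: float) -> ThermalField:
    """Temperature across the gap: linear between the plate temperatures."""
    if T_hot_C < T_cold_C:
        raise ValueError("T_hot must be >= T_cold")
    dT = T_hot_C - T_cold_C
    grad = dT / geometry.gap_um
    T_x = T_cold_C + grad * geometry.x_centers
    return ThermalField(T_cold_C, T_hot_C, T_x, grad)


@dataclass(frozen=True)
class FlowField:
    """Divergence-free convection roll in the vertical slot.

    ``u_x`` is the fully developed vertical velocity profile across the gap
    (um/s, positive upward) away from the ends.  The full 2-D field derives
    from the streamfunction ``psi(x, z) = G(x) * s(z)`` where ``G`` is the
    integral of the slot profile and ``s`` ramps smoothly from 0 at the end
    caps to 1 in the interior over one turning length (~ the gap width):
    the roll closes inside the trap, so no fluid crosses any wall.
    ``uz_face`` (n_z+1, n_x) and ``ux_face`` (n_z, n_x+1) are the face-normal
    velocities used by the finite-volume operator; built from corner values
    of psi they are discretely divergence free to machine precision.
    """

    u_x: np.ndarray
    uz_face: np.ndarray
    ux_face: np.ndarray

    @property
    def peak_speed_um_s(self) -> float:
        return float(np.max(np.abs(self.u_x)))


def _end_ramp(z: np.ndarray, height: float, turning: float) -> np.ndarray:
    """Smoothstep from 0 at both end caps to 1 in the interior."""
    t = np.clip(np.minimum(z, height - z) / turning, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def convection_field(
    geometry: ChamberGeometry,
    thermal: ThermalField,
    fluid: FluidProps,
    turning_length_um: float | None = None,
) -> FlowField:
    """Boussinesq slot convection with end recirculation.

    Returns zero flow for a horizontally oriented chamber (rotating the trap
    by 90 degrees removes the buoyancy drive while leaving thermophoresis
    untouched) and for a vanishing temperature difference.
    """
    if thermal.delta_T < 0:
        raise ValueError("negative temperature difference")
    n_x, n_z = geometry.n_x, geometry.n_z
    if geometry.orientation == "horizontal" or thermal.delta_T == 0:
        return FlowField(
            np.zeros(n_x), np.zeros((n_z + 1, n_x)), np.zeros((n_z, n_x + 1))
        )
    amp = (
        fluid.gravity_um_s2
        * fluid.thermal_expansion_per_K
        * thermal.delta_T
        * geometry.gap_um**2
        / (12.0 * fluid.kinematic_viscosity_um2_s)
    )
    w, H = geometry.gap_um, geometry.height_um
    xt = geometry.x_centers / w
    u = -amp * xt * (1.0 - xt) * (1.0 - 2.0 * xt)
    # the cubic integrates to zero exactly; remove the O(dx^2) quadrature
    # remainder so the discrete cross-sectional flux vanishes on every grid
    u = u - u.mean()

    if turning_length_um is None:
        turning_length_um = min(w, H / 4.0)
    x_edges = np.arange(n_x + 1) * geometry.dx
    z_edges = np.arange(n_z + 1) * geometry.dz
    xe = x_edges / w
    G = -amp * w * 0.5 * xe**2 * (1.0 - xe) ** 2  # integral of the slot cubic
    s = _end_ramp(z_edges, H, turning_length_um)
    psi = s[:, None] * G[None, :]  # (n_z+1, n_x+1) corner streamfunction
    uz_face = (psi[:, 1:] - psi[:, :-1]) / geometry.dx
    ux_face = -(psi[1:, :] - psi[:-1, :]) / geometry.dz
    return FlowField(u, uz_face, ux_face)


@dataclass(frozen=True)
class Species:
    """A solute's transport coefficients and initial concentration.

    ``D_um2_s`` is the diffusion coefficient in the working solution at the
    scenario reference temperature; ``S_T_per_K`` the Soret coefficient
    (positive = accumulates on the cold side); ``c0_uM`` the initial uniform
    concentration.
    """

    name: str
    D_um2_s: float
    S_T_per_K: float
    c0_uM: float = 0.0
    role: str = "protein"

    def __post_init__(self):
        if self.D_um2_s <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.c0_uM < 0:
            raise ValueError("initial concentration must be non-negative")


def drift_field(species: Species, thermal: ThermalField) -> float:
    """Thermophoretic drift velocity across the gap, um/s along +x.

    ``v_T = -D * S_T * dT/dx``; negative for S_T > 0, i.e. toward the cold
    wall at x = 0.
    """
    return -species.D_um2_s * species.S_T_per_K * thermal.grad_K_per_um
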