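"""Temperature-dependent properties of liquid water and Stokes-Einstein helpers.

All transport coefficients in this package are expressed in micrometre /
second / Kelvin units; dynamic viscosity is kept in mPa s (= 1e-3 Pa s) for
the Stokes-Einstein conversions.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, J/K
K_BOLTZMANN = 1.380649e-23

#: Standard gravity, um/s^2 (9.81 m/s^2)
GRAVITY_UM_S2 = 9.81e6

# CRC-style property table for liquid water at atmospheric pressure.
# Columns: T (degC), dynamic viscosity eta (mPa s), density rho (kg/m^3),
# isobaric thermal expansion coefficient beta (1/K).
_T_C = np.array([10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0])
_ETA = np.array([1.3059, 1.1375, 1.0016, 0.8900, 0.7972, 0.7190, 0.6527, 0.5958, 0.5465])
_RHO = np.array([999.70, 999.10, 998.21, 997.05, 995.65, 994.03, 992.22, 990.21, 988.04])
_BETA = np.array([0.88e-4, 1.51e-4, 2.07e-4, 2.57e-4, 3.03e-4, 3.45e-4, 3.85e-4, 4.22e-4, 4.57e-4])


def viscosity_mPa_s(T_C: float) -> float:
    """Dynamic viscosity of water (mPa s), linearly interpolated."""
    return float(np.interp(T_C, _T_C, _ETA))


def density_kg_m3(T_C: float) -> float:
    """Density of water (kg/m^3)."""
    return float(np.interp(T_C, _T_C, _RHO))


def thermal_expansion_per_K(T_C: float) -> float:
    """Isobaric thermal expansion coefficient of water (1/K)."""
    return float(np.interp(T_C, _T_C, _BETA))


def kinematic_viscosity_um2_s(T_C: float, viscosity_factor: float = 1.0) -> float:
    """Kinematic viscosity in um^2/s; `viscosity_factor` scales eta multiplicatively."""
    eta_Pa_s = viscosity_mPa_s(T_C) * 1e-3 * viscosity_factor
    nu_m2_s = eta_Pa_s / density_kg_m3(T_C)
    return nu_m2_s * 1e12


def stokes_einstein_D_um2_s(radius_nm: float, T_C: float, viscosity_factor: float = 1.0) -> float:
    """Diffusion coefficient (um^2/s) of a sphere from the Stokes-Einstein relation.

    ``D = kT / (6 pi eta r)`` with the solution viscosity
    ``eta = viscosity_factor * eta_water(T)``.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    T_K = T_C + 273.15
    eta = viscosity_mPa_s(T_C) * 1e-3 * viscosity_factor
    D_m2_s = K_BOLTZMANN * T_K / (6.0 * np.pi * eta * radius_nm * 1e-9)
    return D_m2_s * 1e12


def rescale_D(D_um2_s: float, T_from_C: float, T_to_C: float) -> float:
    """Rescale a diffusion coefficient between temperatures by T/eta(T).

    Stokes-Einstein temperature scaling with an unchanged hydrodynamic radius
    and an unchanged (dimensionless) viscosity factor, which cancels.
    """
    ratio = ((T_to_C + 273.15) / (T_from_C + 273.15)) * (
        viscosity_mPa_s(T_from_C) / viscosity_mPa_s(T_to_C)
    )
    return D_um2_s * ratio


def hydrodynamic_radius_nm(D_um2_s: float, T_C: float, viscosity_factor: float = 1.0) -> float:
    """Invert Stokes-Einstein: radius (nm) implied by a diffusion coefficient."""
    T_K = T_C + 273.15
    eta = viscosity_mPa_s(T_C) * 1e-3 * viscosity_factor
    r_m = K_BOLTZMANN * T_K / (6.0 * np.pi * eta * D_um2_s * 1e-12)
    return r_m * 1e9
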