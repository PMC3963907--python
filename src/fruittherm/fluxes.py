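"""The four heat-rate operators of the fruit energy budget.

Each boundary face exchanges heat by net radiation (shortwave absorption,
longwave absorption and emission), convection (Whitaker sphere correlation
for the transfer coefficient) and transpiration (latent heat of the vapour
flux, linearised about the dew point).  Interior cells exchange heat by
Fourier conduction with a series (harmonic-path) interface conductivity.
All operators return Watts; signs are positive for heat flowing INTO the
fruit cell, so transpiration enters the budget through its negative.
"""

from __future__ import annotations

import numpy as np

from .environment import CP_AIR, PSYCHROMETRIC_CONSTANT

__all__ = [
    "STEFAN_BOLTZMANN",
    "LATENT_HEAT_VAPORISATION",
    "radiation_power",
    "convective_coefficient",
    "convection_power",
    "transpiration_power",
    "transpiration_mass",
    "interface_conductivity",
    "conduction_power",
    "air_film_properties",
]

STEFAN_BOLTZMANN = 5.67e-8  # W m-2 K-4
#: enthalpy of vaporisation of water, treated as constant (J kg-1)
LATENT_HEAT_VAPORISATION = 2.25e6

# dry-air film properties vs temperature: T (K), k (W m-1 K-1),
# kinematic viscosity nu (m2 s-1), Prandtl number.  Standard dry-air tables.
_AIR_T = np.array([250.0, 275.0, 300.0, 325.0, 350.0])
_AIR_K = np.array([0.0223, 0.0243, 0.0263, 0.0282, 0.0300])
_AIR_NU = np.array([1.135e-5, 1.343e-5, 1.568e-5, 1.804e-5, 2.056e-5])
_AIR_PR = np.array([0.720, 0.713, 0.707, 0.703, 0.700])


def air_film_properties(T_film: float) -> tuple[float, float, float]:
    """(k_air, nu, Pr) of dry air at the film temperature, by interpolation."""
    k = float(np.interp(T_film, _AIR_T, _AIR_K))
    nu = float(np.interp(T_film, _AIR_T, _AIR_NU))
    pr = float(np.interp(T_film, _AIR_T, _AIR_PR))
    return k, nu, pr


def radiation_power(
    S: float,
    A_sw: float,
    A_lw: float,
    emissivity: float,
    R_sw: float,
    Ta: float,
    Ts: float,
) -> float:
    """Net radiative heat rate (W) received by a surface element.

    ``P = S * [(1-A_sw) R_sw + (1-A_lw) sigma Ta^4 - eps sigma Ts^4]``:
    absorbed shortwave, absorbed longwave from a sky/environment radiating at
    air temperature, minus the grey-body emission of the surface.
    """
    if S <= 0:
        raise ValueError("surface area must be positive")
    sig = STEFAN_BOLTZMANN
    return S * (
        (1.0 - A_sw) * R_sw
        + (1.0 - A_lw) * sig * Ta ** 4
        - emissivity * sig * Ts ** 4
    )


def convective_coefficient(
    u: float,
    D: float,
    T_film: float = 293.15,
    viscosity_ratio: float = 1.0,
) -> float:
    """Convective transfer coefficient h (W m-2 K-1), Whitaker sphere form.

    ``Nu = 2 + (0.4 Re^1/2 + 0.06 Re^2/3) Pr^0.4 (mu_inf/mu_s)^1/4`` with the
    viscosity ratio defaulting to 1 (surface and bulk air nearly isothermal
    at fruit temperatures); ``h = Nu k_air / D``.  ``D`` is the
    volume-equivalent sphere diameter of the fruit.
    """
    if u < 0 or D <= 0:
        raise ValueError("need u >= 0 and D > 0")
    k_air, nu_air, pr = air_film_properties(T_film)
    re = u * D / nu_air
    nu = 2.0 + (0.4 * np.sqrt(re) + 0.06 * re ** (2.0 / 3.0)) * pr ** 0.4 * (
        viscosity_ratio ** 0.25
    )
    return float(nu * k_air / D)


def convection_power(h: float, S: float, Ta: float, Ts: float) -> float:
    """Sensible heat rate (W): positive when the air warms the fruit."""
    if h <= 0 or S <= 0:
        raise ValueError("h and S must be positive")
    return S * h * (Ta - Ts)


def transpiration_power(
    S: float,
    Gw: float,
    rho_air: float,
    delta: float,
    Ts: float,
    Td: float,
    clamp: bool = True,
) -> float:
    """Latent heat rate LOST by transpiration (W, >= 0 when clamped).

    Dew-point linearisation of the vapour pressure deficit:
    ``P = S Gw rho_air (Cp_air / tau) Delta (Ts - Td)`` where Delta is the
    saturation-curve slope at the dew point and tau the psychrometric
    constant.  Clamped at zero for Ts < Td (no condensation) unless
    ``clamp=False``.  The caller subtracts this from the heat budget.
    """
    if S < 0 or Gw < 0:
        raise ValueError("S and Gw must be non-negative")
    p = S * Gw * rho_air * (CP_AIR / PSYCHROMETRIC_CONSTANT) * delta * (Ts - Td)
    if clamp:
        p = max(0.0, p)
    return float(p)


def transpiration_mass(energy: float) -> float:
    """Water mass (kg) evaporated by ``energy`` joules of latent heat."""
    if energy < 0:
        raise ValueError("latent energy must be non-negative")
    return energy / LATENT_HEAT_VAPORISATION


def interface_conductivity(K1: float, K2: float, e1: float, e2: float) -> float:
    """Series conductivity between two cells across their shared face.

    ``K = (e1+e2) / (e1/K1 + e2/K2)`` — the thickness-weighted harmonic
    composition of the two half-path conductivities; reduces to the harmonic
    mean for e1 = e2 and to K1 scaled by the full path when K2 is a perfect
    conductor.
    """
    if K1 <= 0 or K2 <= 0:
        raise ValueError("conductivities must be positive")
    if e1 <= 0 or e2 <= 0:
        raise ValueError("half-path lengths must be positive")
    return (e1 + e2) / (e1 / K1 + e2 / K2)


def conduction_power(K: float, S: float, dT: float, distance: float) -> float:
    """Fourier conduction (W) into the cell across one face.

    ``P = K S dT / distance`` with ``dT`` the neighbour-minus-self
    temperature difference, so the pairwise exchange is antisymmetric.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    return K * S * dT / distance
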