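"""Thermal, optical and colour properties of fruit tissues.

Thermal conductivity and heat capacity are estimated from tissue water
content by linear correlations (Valente-Nicolas-style for K, Siebel for Cp);
tissue density comes from an Archimedes buoyancy measurement.  Surface cells
mix peel and pulp in proportion to the peel volume fraction.  Optical
properties are the broadband shortwave reflectance (irradiance-weighted mean
of the peel reflectance spectrum over 350-2500 nm), the longwave reflectance
via Kirchhoff's law, and CIELAB colour coordinates derived from the same
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _cie

__all__ = [
    "TissueProperties",
    "SurfaceProperties",
    "ReflectanceSpectrum",
    "ColourCoords",
    "conductivity_from_water",
    "heat_capacity_from_water",
    "specific_gravity_archimedes",
    "blend_boundary_cell",
    "shortwave_reflectance",
    "longwave_reflectance",
    "hue_chroma",
    "reflectance_to_lab",
    "DEFAULT_K_COEFFS",
    "DEFAULT_CP_COEFFS",
]

#: default linear water-content -> conductivity coefficients (W m-1 K-1)
DEFAULT_K_COEFFS = (0.148, 0.493)
#: Siebel's above-freezing correlation for foodstuffs (J kg-1 K-1)
DEFAULT_CP_COEFFS = (837.4, 3349.0)


@dataclass(frozen=True)
class TissueProperties:
    """Bulk properties of one tissue (stone, pulp or peel)."""

    K: float  # thermal conductivity, W m-1 K-1
    Cp: float  # heat capacity, J kg-1 K-1
    Sg: float  # specific gravity (density), kg m-3
    xw: float = np.nan  # water mass fraction, optional bookkeeping

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.Cp > 0 and self.Sg > 0):
            raise ValueError("K, Cp and Sg must be positive")
        if not np.isnan(self.xw) and not 0.0 <= self.xw <= 1.0:
            raise ValueError("water content must lie in [0, 1]")

    @classmethod
    def from_water_content(
        cls,
        xw: float,
        Sg: float,
        k_coeffs: tuple[float, float] = DEFAULT_K_COEFFS,
        cp_coeffs: tuple[float, float] = DEFAULT_CP_COEFFS,
    ) -> "TissueProperties":
        return cls(
            K=conductivity_from_water(xw, k_coeffs),
            Cp=heat_capacity_from_water(xw, cp_coeffs),
            Sg=Sg,
            xw=xw,
        )


@dataclass(frozen=True)
class SurfaceProperties:
    """Radiative/evaporative surface properties of one fruit side.

    ``A_lw`` is tied to the emissivity by Kirchhoff's law and is therefore
    derived, never stored independently.
    """

    A_sw: float  # shortwave reflectance
    emissivity: float
    Gw: float  # surface conductance to water vapour, m s-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.A_sw <= 1.0:
            raise ValueError("A_sw must lie in [0, 1]")
        if not 0.0 <= self.emissivity <= 1.0:
            raise ValueError("emissivity must lie in [0, 1]")
        if self.Gw < 0:
            raise ValueError("Gw must be non-negative")

    @property
    def A_lw(self) -> float:
        return longwave_reflectance(self.emissivity)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Peel reflectance paired with a solar spectral irradiance on one grid."""

    wavelength_nm: np.ndarray
    reflectance: np.ndarray
    irradiance: np.ndarray | None = None  # W m-2 nm-1

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "reflectance", r)
        if wl.shape != r.shape:
            raise ValueError("wavelength and reflectance grids are misaligned")
        if self.irradiance is not None:
            irr = np.asarray(self.irradiance, dtype=float)
            object.__setattr__(self, "irradiance", irr)
            if irr.shape != wl.shape:
                raise ValueError("irradiance grid is misaligned")
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("reflectance values must lie in [0, 1]")


@dataclass(frozen=True)
class ColourCoords:
    """Polar CIELAB colour descriptors."""

    a: float
    b: float
    chroma: float
    hue_deg: float


def conductivity_from_water(
    xw: float, coeffs: tuple[float, float] = DEFAULT_K_COEFFS
) -> float:
    """Thermal conductivity K = c0 + c1*xw from water mass fraction."""
    if not 0.0 <= xw <= 1.0:
        raise ValueError(f"water content must lie in [0, 1], got {xw}")
    c0, c1 = coeffs
    return c0 + c1 * xw


def heat_capacity_from_water(
    xw: float, coeffs: tuple[float, float] = DEFAULT_CP_COEFFS
) -> float:
    """Heat capacity Cp = d0 + d1*xw (Siebel's above-freezing form)."""
    if not 0.0 <= xw <= 1.0:
        raise ValueError(f"water content must lie in [0, 1], got {xw}")
    d0, d1 = coeffs
    return d0 + d1 * xw


def specific_gravity_archimedes(
    mass: float, upthrust: float, sg_water: float = 1000.0
) -> float:
    """Density from an Archimedes weighing: Sg = m * Sg_water / r.

    ``mass`` is the fresh mass in air (kg) and ``upthrust`` the upward force
    (expressed in kg) when the organ is fully immersed.
    """
    if upthrust <= 0:
        raise ValueError("upthrust must be positive")
    return mass * sg_water / upthrust


def blend_boundary_cell(
    peel_frac: float, peel: TissueProperties, pulp: TissueProperties
) -> TissueProperties:
    """Volume-fraction-weighted mix of peel and pulp for a surface cell."""
    if not 0.0 <= peel_frac <= 1.0:
        raise ValueError("peel fraction must lie in [0, 1]")
    f = peel_frac

    def mix(a: float, b: float) -> float:
        return f * a + (1.0 - f) * b

    return TissueProperties(
        K=mix(peel.K, pulp.K),
        Cp=mix(peel.Cp, pulp.Cp),
        Sg=mix(peel.Sg, pulp.Sg),
        xw=mix(peel.xw, pulp.xw),
    )


def shortwave_reflectance(spec: ReflectanceSpectrum) -> float:
    """Broadband shortwave reflectance, the irradiance-weighted spectral mean.

    ``A_sw = trapz(R * I) / trapz(I)`` over the measured grid (nominally
    350-2500 nm).
    """
    if spec.irradiance is None:
        raise ValueError("spectrum carries no solar irradiance")
    if spec.wavelength_nm.size < 2:
        raise ValueError("need at least two wavelengths")
    denom = np.trapezoid(spec.irradiance, spec.wavelength_nm)
    if denom <= 0:
        raise ValueError("total irradiance is zero; reflectance undefined")
    num = np.trapezoid(spec.reflectance * spec.irradiance, spec.wavelength_nm)
    return float(num / denom)


def longwave_reflectance(emissivity: float) -> float:
    """Kirchhoff's law: A_lw = 1 - emissivity."""
    if not 0.0 <= emissivity <= 1.0:
        raise ValueError("emissivity must lie in [0, 1]")
    return 1.0 - emissivity


def hue_chroma(a: float, b: float) -> ColourCoords:
    """Polar form of the CIELAB (a, b) plane.

    Chroma is the radius sqrt(a^2 + b^2); the hue angle is the quadrant-
    correct arctangent of (b, a) mapped to [0, 360) degrees.
    """
    chroma = float(np.hypot(a, b))
    hue = float(np.degrees(np.arctan2(b, a))) % 360.0
    return ColourCoords(a=a, b=b, chroma=chroma, hue_deg=hue)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(
        t > delta ** 3, np.cbrt(t), t / (3 * delta ** 2) + 4.0 / 29.0
    )


def reflectance_to_lab(
    spec: ReflectanceSpectrum,
) -> tuple[float, float, float]:
    """CIELAB (L*, a*, b*) of a reflectance spectrum under D65, 2 deg observer.

    The reflectance is interpolated onto the built-in 10 nm colorimetric grid
    (380-730 nm); tristimulus values use the standard summation with the
    illuminant normalised so that a perfect reflector has Y = 100.
    """
    wl = spec.wavelength_nm
    if wl.min() > 400 or wl.max() < 700:
        raise ValueError("spectrum must cover the visible range (400-700 nm)")
    grid = _cie.WAVELENGTHS
    r = np.interp(grid, wl, spec.reflectance)
    illum = _cie.D65
    k = 100.0 / np.sum(illum * _cie.YBAR)
    X = k * np.sum(r * illum * _cie.XBAR)
    Y = k * np.sum(r * illum * _cie.YBAR)
    Z = k * np.sum(r * illum * _cie.ZBAR)
    Xn = k * np.sum(illum * _cie.XBAR)
    Yn = 100.0
    Zn = k * np.sum(illum * _cie.ZBAR)
    fx, fy, fz = _lab_f(np.array([X / Xn, Y / Yn, Z / Zn]))
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return float(L), float(a), float(b)
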