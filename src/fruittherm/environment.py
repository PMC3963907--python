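"""Atmospheric forcing: weather series, psychrometrics and solar partitioning.

Weather is an hourly (or finer) series of air temperature, humidity, global
shortwave irradiance and wind speed, either read from CSV or synthesised as
an idealised diurnal cycle.  Psychrometric helpers provide the Buck (1981)
saturation vapour pressure and its slope, dew point, and CIPM-2007 moist-air
density — the ingredients of the latent-heat (transpiration) flux.  Incident
shortwave radiation is partitioned between the fixed sunny and shaded fruit
sides; the shaded side receives a flat 20 % of the global radiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeatherRecord",
    "WeatherSeries",
    "saturation_vapour_pressure",
    "svp_slope_at",
    "dew_point",
    "air_density",
    "partition_shortwave",
    "synthesize_weather",
    "solar_direction",
    "PSYCHROMETRIC_CONSTANT",
    "CP_AIR",
    "SHADED_FRACTION",
]

#: psychrometric constant tau (Pa K-1)
PSYCHROMETRIC_CONSTANT = 66.5
#: heat capacity of air (J kg-1 K-1)
CP_AIR = 1004.0
#: fraction of global radiation received by the shaded fruit side
SHADED_FRACTION = 0.20

_T0C = 273.15
# Buck (1981) over-water coefficients
_BUCK_A = 611.21
_BUCK_B = 17.502
_BUCK_C = 240.97


@dataclass(frozen=True)
class WeatherRecord:
    """One instant of forcing; temperatures in Kelvin, time in seconds."""

    time: float
    Ta: float
    RH: float  # percent
    R_glob: float  # W m-2
    u: float  # m s-1
    pressure: float = 101325.0

    def __post_init__(self) -> None:
        if self.Ta <= 0:
            raise ValueError("air temperature must be positive (Kelvin)")
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError("relative humidity must lie in [0, 100] %")
        if self.R_glob < 0 or self.u < 0:
            raise ValueError("irradiance and wind speed must be non-negative")

    @property
    def Td(self) -> float:
        return dew_point(self.Ta, self.RH)


@dataclass
class WeatherSeries:
    """Time-stamped forcing channels; time in seconds since run start."""

    time: np.ndarray
    Ta: np.ndarray  # K
    RH: np.ndarray  # percent
    R_glob: np.ndarray  # W m-2
    u: np.ndarray  # m s-1
    pressure: float = 101325.0

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("Ta", "RH", "R_glob", "u"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def interpolate(self, t: float) -> WeatherRecord:
        """Linear interpolation of every channel at time ``t`` (seconds)."""
        t0, t1 = self.span
        if not t0 <= t <= t1:
            raise ValueError(f"t={t} outside weather span [{t0}, {t1}]")
        return WeatherRecord(
            time=t,
            Ta=float(np.interp(t, self.time, self.Ta)),
            RH=float(np.interp(t, self.time, self.RH)),
            R_glob=float(np.interp(t, self.time, self.R_glob)),
            u=float(np.interp(t, self.time, self.u)),
            pressure=self.pressure,
        )

    # -- CSV interface ---------------------------------------------------
    # columns: time_s, Ta_C, RH_pct, Rglob_Wm2, wind_ms [, pressure_Pa]
    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "time_s": self.time,
                "Ta_C": self.Ta - _T0C,
                "RH_pct": self.RH,
                "Rglob_Wm2": self.R_glob,
                "wind_ms": self.u,
                "pressure_Pa": self.pressure,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path)
        required = ["time_s", "Ta_C", "RH_pct", "Rglob_Wm2", "wind_ms"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"weather CSV missing columns: {missing}")
        pressure = (
            float(df["pressure_Pa"].iloc[0])
            if "pressure_Pa" in df.columns
            else 101325.0
        )
        return cls(
            time=df["time_s"].to_numpy(float),
            Ta=df["Ta_C"].to_numpy(float) + _T0C,
            RH=df["RH_pct"].to_numpy(float),
            R_glob=df["Rglob_Wm2"].to_numpy(float),
            u=df["wind_ms"].to_numpy(float),
            pressure=pressure,
        )


def _check_temperature(T: float) -> None:
    if not 233.0 < T < 333.0:
        raise ValueError(f"temperature {T} K outside psychrometric range")


def saturation_vapour_pressure(T: float) -> float:
    """Buck (1981) saturation vapour pressure over water, in Pa.

    ``es = 611.21 * exp(17.502 t / (240.97 + t))`` with t in Celsius.
    """
    _check_temperature(T)
    t = T - _T0C
    return _BUCK_A * np.exp(_BUCK_B * t / (_BUCK_C + t))


def svp_slope_at(T: float) -> float:
    """Analytic derivative of the Buck curve, Pa K-1."""
    _check_temperature(T)
    t = T - _T0C
    es = _BUCK_A * np.exp(_BUCK_B * t / (_BUCK_C + t))
    return es * _BUCK_B * _BUCK_C / (_BUCK_C + t) ** 2


def dew_point(Ta: float, RH: float) -> float:
    """Dew point (K) from air temperature and relative humidity.

    Analytic inversion of the Buck curve at the ambient vapour pressure
    ``ea = RH/100 * es(Ta)``.
    """
    if not 0.0 < RH <= 100.0:
        raise ValueError("relative humidity must lie in (0, 100] %")
    ea = RH / 100.0 * saturation_vapour_pressure(Ta)
    y = np.log(ea / _BUCK_A)
    t = _BUCK_C * y / (_BUCK_B - y)
    return float(t + _T0C)


# CIPM-2007 moist-air density (Picard et al.) constants
_R_GAS = 8.314472
_M_AIR = 28.96546e-3  # kg mol-1 at standard CO2 content
_M_WATER = 18.01528e-3


def _cipm_psv(T: float) -> float:
    A, B, C, D = 1.2378847e-5, -1.9121316e-2, 33.93711047, -6343.1645
    return np.exp(A * T * T + B * T + C + D / T)


def air_density(
    Ta: float, pressure: float = 101325.0, RH: float = 0.0, method: str = "cipm"
) -> float:
    """Moist-air density (kg m-3) by the CIPM-2007 formulation.

    ``method='ideal'`` falls back to the dry ideal-gas law P/(R_s T).
    """
    if method == "ideal":
        return pressure * _M_AIR / (_R_GAS * Ta)
    t = Ta - _T0C
    p = pressure
    # enhancement factor and molar fraction of water vapour
    f = 1.00062 + 3.14e-8 * p + 5.6e-7 * t * t
    xv = RH / 100.0 * f * _cipm_psv(Ta) / p
    # compressibility
    a0, a1, a2 = 1.58123e-6, -2.9331e-8, 1.1043e-10
    b0, b1 = 5.707e-6, -2.051e-8
    c0, c1 = 1.9898e-4, -2.376e-6
    d, e = 1.83e-11, -0.765e-8
    Z = (
        1.0
        - (p / Ta)
        * (a0 + a1 * t + a2 * t * t + (b0 + b1 * t) * xv + (c0 + c1 * t) * xv * xv)
        + (p / Ta) ** 2 * (d + e * xv * xv)
    )
    return (
        p * _M_AIR / (Z * _R_GAS * Ta) * (1.0 - xv * (1.0 - _M_WATER / _M_AIR))
    )


def partition_shortwave(
    R_glob: float,
    side: str,
    face_normal: np.ndarray | None = None,
    sun_direction: np.ndarray | None = None,
    diffuse_fraction: float = 0.15,
    shaded_fraction: float = SHADED_FRACTION,
) -> float:
    """Incident shortwave irradiance (W m-2) on one boundary face.

    Shaded faces receive a flat ``shaded_fraction`` (default 20 %) of the
    global radiation.  Sunny faces receive the diffuse component plus the
    direct beam weighted by the cosine of the face-normal/sun angle.
    """
    if R_glob < 0:
        raise ValueError("global radiation must be non-negative")
    if R_glob == 0.0:
        return 0.0
    if side == "shaded":
        return shaded_fraction * R_glob
    if side != "sunny":
        raise ValueError(f"unknown side {side!r}")
    if face_normal is None or sun_direction is None:
        cos = 1.0
    else:
        n = np.asarray(face_normal, float)
        s = np.asarray(sun_direction, float)
        cos = max(0.0, float(n @ s) / (np.linalg.norm(n) * np.linalg.norm(s)))
    return diffuse_fraction * R_glob + (1.0 - diffuse_fraction) * R_glob * cos


def solar_direction(
    hour: float, latitude_deg: float = -21.0, day_of_year: int = 15
) -> np.ndarray:
    """Unit vector toward the sun from a declination / hour-angle model.

    A deliberately simple pluggable default: x points toward the equator-side
    horizon azimuth of the site, z is up.  Returns the upward-pointing sun
    vector, or a horizon direction at night.
    """
    decl = np.radians(23.45) * np.sin(2 * np.pi * (284 + day_of_year) / 365.0)
    lat = np.radians(latitude_deg)
    ha = np.radians(15.0 * (hour - 12.0))
    sin_el = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    el = np.arcsin(np.clip(sin_el, -1.0, 1.0))
    az = ha  # crude east-west sweep; adequate for a cosine weighting
    v = np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), max(np.sin(el), 0.0)]
    )
    return v / np.linalg.norm(v)


def synthesize_weather(
    days: float = 1.0,
    timestep: float = 3600.0,
    t_min_c: float = 16.0,
    t_max_c: float = 30.0,
    rh_min: float = 40.0,
    rh_max: float = 90.0,
    peak_irradiance: float = 900.0,
    wind: float = 1.5,
    wind_noise: float = 0.0,
    seed: int = 0,
    dawn_h: float = 6.0,
    dusk_h: float = 18.0,
    peak_temp_h: float = 15.0,
    pressure: float = 101325.0,
) -> WeatherSeries:
    """Idealised diurnal weather: a synthetic stand-in for station data.

    Air temperature follows a piecewise half-cosine with its minimum at dawn
    and maximum in mid-afternoon; relative humidity is in anti-phase; global
    irradiance is a half-sine over the daylight window; wind is constant plus
    optional seeded Gaussian noise.  Deterministic for a given seed.
    """
    if t_min_c > t_max_c:
        raise ValueError("t_min_c must not exceed t_max_c")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, days * 86400.0 + 0.5 * timestep, timestep)
    hour = (time / 3600.0) % 24.0

    # phase in [0, 1): 0 at dawn (minimum), 0.5 at peak_temp_h (maximum)
    rise = (hour - dawn_h) % 24.0
    rise_len = (peak_temp_h - dawn_h) % 24.0
    fall_len = 24.0 - rise_len
    phase = np.where(
        rise <= rise_len,
        0.5 * rise / rise_len,
        0.5 + 0.5 * (rise - rise_len) / fall_len,
    )
    shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # 0 at dawn, 1 at peak
    Ta = t_min_c + (t_max_c - t_min_c) * shape + _T0C
    RH = rh_max - (rh_max - rh_min) * shape

    daylight = (hour >= dawn_h) & (hour <= dusk_h)
    R_glob = np.where(
        daylight,
        peak_irradiance * np.sin(np.pi * (hour - dawn_h) / (dusk_h - dawn_h)),
        0.0,
    )
    R_glob = np.clip(R_glob, 0.0, None)

    u = np.full_like(time, float(wind))
    if wind_noise > 0:
        u = np.clip(u + rng.normal(0.0, wind_noise, size=u.shape), 0.0, None)

    return WeatherSeries(
        time=time, Ta=Ta, RH=RH, R_glob=R_glob, u=u, pressure=pressure
    )
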