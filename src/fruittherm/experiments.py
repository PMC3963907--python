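"""Computational experiments: validation, sensitivity and development runs.

Three experiments exercise the model end to end:

* sphere validation — the solver is run on a homogeneous sphere heated by a
  constant convective boundary and compared with the classical transient-
  conduction eigenfunction series (one-term family with eigenvalues from
  ``1 - z cot z = Bi``), the standard verification for conduction codes;
* one-at-a-time sensitivity — every model parameter is perturbed by +/-20 %
  around a base diurnal run and a dimensionless sensitivity coefficient
  ``SC = [(out(+) - out(-)) / out(base)] / 0.4`` is reported per output and
  fruit position.  Transpiration is structurally linear in the surface
  conductance Gw, so its SC is 1 up to the (small) thermal feedback;
* development experiment — a season-long run in which size and property
  trajectories can be frozen one at a time at their initial (M1) values, to
  attribute seasonal temperature/transpiration changes to fruit expansion
  versus property evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (
    RunConfig,
    build_env_params,
    build_mesh,
    build_solver_config,
    build_surfaces,
    build_tissues,
    build_weather,
)
from .environment import WeatherSeries, synthesize_weather
from .geometry import BOUNDARY, Ellipsoid, StoneGeometry, build_fruit_mesh, grow_mesh
from .properties import SurfaceProperties, TissueProperties
from .schedules import DevelopmentSchedule, default_mango_schedule
from .solver import EnvironmentParams, SimulationResult, SolverConfig, simulate

__all__ = [
    "SphereCase",
    "SphereValidation",
    "FieldStatistics",
    "analytic_sphere_temperature",
    "run_sphere_validation",
    "goodness_of_fit",
    "sensitivity_analysis",
    "run_development_experiment",
    "field_statistics",
    "DEVELOPMENT_VARIANTS",
]

_T0C = 273.15


@dataclass(frozen=True)
class SphereCase:
    """Homogeneous sphere under constant convective heating.

    Radius 4 mm, initial 16 degC, ambient 20 degC, h = 5 W m-2 K-1,
    Cp = 3600 J kg-1 K-1, k = 0.1 W m-1 K-1 give Biot = hR/k = 0.2.  The
    density is not part of the dimensionless problem (it only sets the time
    scale identically in solver and series); 1000 kg m-3 is used in both.
    """

    R: float = 4e-3
    T0: float = 16.0 + _T0C
    Ta: float = 20.0 + _T0C
    h: float = 5.0
    Cp: float = 3600.0
    k: float = 0.1
    rho: float = 1000.0

    @property
    def biot(self) -> float:
        return self.h * self.R / self.k

    @property
    def diffusivity(self) -> float:
        return self.k / (self.rho * self.Cp)

    @property
    def lumped_time_constant(self) -> float:
        return self.rho * self.Cp * self.R / (3.0 * self.h)


def _sphere_eigenvalues(biot: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` roots of 1 - z cot z = Bi (z_n in (n pi, (n+1) pi))."""

    def f(z: float) -> float:
        return 1.0 - z / np.tan(z) - biot

    roots = []
    eps = 1e-9
    for n in range(n_terms):
        lo, hi = n * np.pi + eps, (n + 1) * np.pi - eps
        roots.append(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15))
    return np.array(roots)


def analytic_sphere_temperature(
    r: np.ndarray | float,
    t: np.ndarray | float,
    case: SphereCase | None = None,
    n_terms: int = 80,
) -> np.ndarray:
    """Series solution T(r, t) for the convectively heated sphere (K).

    ``theta = sum_n C_n exp(-z_n^2 Fo) sin(z_n r~)/(z_n r~)`` with
    ``C_n = 4 (sin z_n - z_n cos z_n) / (2 z_n - sin 2 z_n)``, Fourier number
    ``Fo = alpha t / R^2`` and ``r~ = r/R``; broadcast over r and t.
    """
    case = case or SphereCase()
    r = np.asarray(r, float)
    t = np.asarray(t, float)
    if np.any(r < 0) or np.any(r > case.R * (1 + 1e-12)):
        raise ValueError("radius outside [0, R]")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    z = _sphere_eigenvalues(case.biot, n_terms)
    cn = 4.0 * (np.sin(z) - z * np.cos(z)) / (2.0 * z - np.sin(2.0 * z))
    r_b, t_b = np.broadcast_arrays(np.atleast_1d(r), np.atleast_1d(t))
    zr = (r_b / case.R)[..., None] * z
    # sinc form, safe at the centre
    radial = np.where(zr < 1e-12, 1.0, np.sin(zr) / np.where(zr == 0, 1.0, zr))
    fo = (case.diffusivity * t_b / case.R ** 2)[..., None]
    theta = np.sum(cn * np.exp(-z * z * fo) * radial, axis=-1)
    out = case.Ta + (case.T0 - case.Ta) * theta
    return out if np.ndim(r) or np.ndim(t) else float(out[0])


@dataclass(frozen=True)
class SphereValidation:
    rmse: float
    r2: float
    n_cells: int
    times: np.ndarray
    simulated: np.ndarray  # (2, n) surface, centre
    analytic: np.ndarray


def run_sphere_validation(
    case: SphereCase | None = None,
    target_cells: int = 800,
    n_samples: int = 100,
    horizon_time_constants: float = 5.0,
) -> SphereValidation:
    """Run the full solver on the sphere case and score it against the series.

    Radiation and transpiration are switched off (perfectly reflective,
    non-emissive, impermeable surface), the convective coefficient is held at
    the prescribed constant, and surface/centre temperatures are sampled on a
    uniform grid out to five lumped time constants.  The analytic series is
    evaluated at the actual sampled radii (mean boundary-cell radius and the
    centre cell's radius), so the comparison isolates the integration error.
    """
    case = case or SphereCase()
    mesh = build_fruit_mesh(
        Ellipsoid(case.R, case.R, case.R),
        StoneGeometry(0.0, 0.0, 0.0),
        peel_thickness=case.R * 1e-3,
        target_cells=target_cells,
        sun_normal=(1.0, 1.0, 1.0),
    )
    tp = TissueProperties(K=case.k, Cp=case.Cp, Sg=case.rho)
    tissues = {"pulp": tp, "peel": tp, "stone": tp}
    sp = SurfaceProperties(A_sw=1.0, emissivity=0.0, Gw=0.0)
    surfaces = {"sunny": sp, "shaded": sp}

    horizon = horizon_time_constants * case.lumped_time_constant
    weather = WeatherSeries(
        time=np.array([0.0, horizon]),
        Ta=np.full(2, case.Ta),
        RH=np.full(2, 50.0),
        R_glob=np.zeros(2),
        u=np.zeros(2),
    )
    cadence = horizon / n_samples
    result = simulate(
        mesh,
        tissues,
        surfaces,
        weather,
        solver=SolverConfig(
            output_cadence=cadence, initial_temperature=case.T0, store_fields=True
        ),
        env=EnvironmentParams(fixed_h=case.h),
    )

    boundary = mesh.labels == BOUNDARY
    radii = np.linalg.norm(mesh.centres, axis=1)
    r_surf = float(radii[boundary].mean())
    centre = mesh.centre_cell()
    r_centre = float(radii[centre])

    sim_surface = result.T_fields[:, boundary].mean(axis=1)
    sim_centre = result.T_fields[:, centre]
    ana_surface = analytic_sphere_temperature(r_surf, result.times, case)
    ana_centre = analytic_sphere_temperature(r_centre, result.times, case)

    simulated = np.stack([sim_surface, sim_centre])
    analytic = np.stack([ana_surface, ana_centre])
    rmse, r2 = goodness_of_fit(analytic.ravel(), simulated.ravel())
    return SphereValidation(
        rmse=rmse,
        r2=r2,
        n_cells=mesh.n_cells,
        times=result.times,
        simulated=simulated,
        analytic=analytic,
    )


def goodness_of_fit(
    observed: np.ndarray,
    simulated: np.ndarray,
    r2_method: str = "pearson",
) -> tuple[float, float]:
    """(RMSE, R2) between a reference and a simulated series.

    RMSE = sqrt(mean((y - y_hat)^2)); R2 is the squared Pearson correlation
    by default, or ``1 - SS_res/SS_tot`` with ``r2_method='explained'``.
    Returns NaN for R2 when either series has zero variance.
    """
    y = np.asarray(observed, float)
    yh = np.asarray(simulated, float)
    if y.shape != yh.shape:
        raise ValueError("series length mismatch")
    if y.size < 2:
        raise ValueError("need at least two points")
    rmse = float(np.sqrt(np.mean((y - yh) ** 2)))
    if np.std(y) == 0 or np.std(yh) == 0:
        return rmse, float("nan")
    if r2_method == "pearson":
        r2 = float(np.corrcoef(y, yh)[0, 1] ** 2)
    elif r2_method == "explained":
        r2 = float(1.0 - np.sum((y - yh) ** 2) / np.sum((y - y.mean()) ** 2))
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return rmse, r2


# -- one-at-a-time sensitivity -------------------------------------------

SENSITIVITY_PARAMETERS = (
    "Cp",
    "A_sw",
    "Sg",
    "Gw",
    "K",
    "peel_thickness",
    "stone_ratio",
    "fruit_size",
)


def _perturbed_config(cfg: RunConfig, param: str, factor: float) -> RunConfig:
    out = cfg.model_copy(deep=True)
    p = out.properties
    if param == "Cp":
        p.heat_capacity_coeffs = tuple(c * factor for c in p.heat_capacity_coeffs)
    elif param == "K":
        p.conductivity_coeffs = tuple(c * factor for c in p.conductivity_coeffs)
    elif param == "Sg":
        for t in ("pulp", "peel", "stone"):
            getattr(p, t).Sg *= factor
    elif param == "A_sw":
        for s in ("sunny", "shaded"):
            getattr(p, s).A_sw = min(1.0, getattr(p, s).A_sw * factor)
    elif param == "Gw":
        for s in ("sunny", "shaded"):
            getattr(p, s).Gw *= factor
    elif param == "peel_thickness":
        out.geometry.peel_thickness *= factor
    elif param == "stone_ratio":
        out.geometry.stone_ratios = tuple(
            r * factor for r in out.geometry.stone_ratios
        )
    elif param == "fruit_size":
        out.geometry.semi_axes = tuple(a * factor for a in out.geometry.semi_axes)
    else:
        raise ValueError(f"unknown parameter {param!r}")
    return out


def _run_outputs(cfg: RunConfig, weather: WeatherSeries) -> dict[str, float]:
    """Scalar outputs of one diurnal run, keyed (position, statistic)."""
    from .config import run_simulation

    res = run_simulation(cfg, weather=weather)
    out: dict[str, float] = {}
    series = {
        "centre": res.centre_T - _T0C,
        "sunny": res.side_mean["sunny"] - _T0C,
        "shaded": res.side_mean["shaded"] - _T0C,
    }
    for pos, s in series.items():
        out[f"T_max@{pos}"] = float(s.max())
        out[f"T_mean@{pos}"] = float(s.mean())
        out[f"T_min@{pos}"] = float(s.min())
    for side in ("sunny", "shaded"):
        # L m-2 h-1 (1 kg of water = 1 L)
        out[f"transp_max@{side}"] = float(res.transp_rate[side].max() * 3600.0)
    return out


def sensitivity_analysis(
    cfg: RunConfig,
    parameters: tuple[str, ...] = SENSITIVITY_PARAMETERS,
    perturbation: float = 0.2,
    weather: WeatherSeries | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity coefficients over +/-``perturbation``.

    For each parameter the model is run at (1-p) and (1+p) times the base
    value with everything else fixed, and each output's central relative
    change is divided by the total relative parameter change (2p = 0.4 by
    default).  Returns a tidy frame (parameter, output, sc, base, low, high);
    a failed perturbed run flags the affected rows with NaN instead of
    aborting the analysis.
    """
    unknown = set(parameters) - set(SENSITIVITY_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    weather = weather if weather is not None else build_weather(cfg)
    base = _run_outputs(cfg, weather)
    rows = []
    for param in parameters:
        try:
            lo = _run_outputs(_perturbed_config(cfg, param, 1.0 - perturbation), weather)
            hi = _run_outputs(_perturbed_config(cfg, param, 1.0 + perturbation), weather)
        except Exception:  # noqa: BLE001 - flagged, not fatal
            for key in base:
                rows.append(
                    {"parameter": param, "output": key, "sc": np.nan,
                     "base": base[key], "low": np.nan, "high": np.nan}
                )
            continue
        for key, b in base.items():
            sc = (hi[key] - lo[key]) / b / (2.0 * perturbation) if b != 0 else np.nan
            rows.append(
                {"parameter": param, "output": key, "sc": sc,
                 "base": b, "low": lo[key], "high": hi[key]}
            )
    return pd.DataFrame(rows)


# -- development experiment ----------------------------------------------

DEVELOPMENT_VARIANTS: dict[str, set[str]] = {
    "evolving": set(),
    "all_fixed": {"size", "gw", "a_sw", "thermal"},
    "size_fixed": {"size"},
    "gw_fixed": {"gw"},
    "a_sw_fixed": {"a_sw"},
    "thermal_fixed": {"thermal"},
}


def run_development_experiment(
    cfg: RunConfig,
    schedule: DevelopmentSchedule | None = None,
    weather: WeatherSeries | None = None,
    variants: dict[str, set[str]] | None = None,
    dab_start: float | None = None,
    dab_end: float | None = None,
) -> pd.DataFrame:
    """Season-long runs with property trajectories selectively frozen at M1.

    The configured semi-axes describe the MATURE fruit; the starting mesh is
    obtained by dividing by the schedule's final size scale, so that growth
    ends at the configured size.  Each variant freezes a channel subset of
    the schedule at its first-stage value.  Returns one row per variant with
    mean/max/min temperature (degC), the maximum transpiration per surface
    unit (L m-2 h-1) and the total seasonal water loss (L).
    """
    schedule = schedule or default_mango_schedule()
    variants = variants or DEVELOPMENT_VARIANTS
    lo, hi = schedule.span
    dab_start = lo if dab_start is None else dab_start
    dab_end = hi if dab_end is None else dab_end
    n_days = dab_end - dab_start
    if weather is None:
        syn = cfg.environment.synthetic
        weather = synthesize_weather(
            days=n_days,
            timestep=syn.timestep_s,
            t_min_c=syn.t_min_c,
            t_max_c=syn.t_max_c,
            rh_min=syn.rh_min,
            rh_max=syn.rh_max,
            peak_irradiance=syn.peak_irradiance,
            wind=syn.wind,
            wind_noise=syn.wind_noise,
            seed=cfg.seed,
            pressure=cfg.environment.pressure,
        )

    final_scale = schedule.at(hi).size_scale
    m1_axes = tuple(a / final_scale for a in cfg.geometry.semi_axes)
    fruit = Ellipsoid(*m1_axes)
    stone = StoneGeometry.from_ratios(fruit, cfg.geometry.stone_ratios)
    from .config import _sun_vectors

    split, _ = _sun_vectors(cfg.geometry)
    base_mesh = build_fruit_mesh(
        fruit, stone, cfg.geometry.peel_thickness, cfg.geometry.target_cells, split
    )
    solver = build_solver_config(cfg)
    solver.store_fields = False
    env = build_env_params(cfg)

    rows = []
    for name, channels in variants.items():
        sched = schedule.fixed(channels) if channels else schedule
        res = simulate(
            base_mesh,
            {},  # tissues come from the schedule
            {},
            weather,
            solver=solver,
            env=env,
            schedule=sched,
            dab_start=dab_start,
        )
        max_tr = max(
            float(res.transp_rate["sunny"].max()),
            float(res.transp_rate["shaded"].max()),
        ) * 3600.0
        rows.append(
            {
                "variant": name,
                "T_mean_C": float(res.T_mean.mean()) - _T0C,
                "T_max_C": float(res.T_max.max()) - _T0C,
                "T_min_C": float(res.T_min.min()) - _T0C,
                "transp_max_L_m2_h": max_tr,
                "total_water_L": res.final_state.water_total,  # 1 kg = 1 L
            }
        )
    return pd.DataFrame(rows).set_index("variant")


@dataclass(frozen=True)
class FieldStatistics:
    """Spatial statistics of one stored snapshot."""

    time: float
    t_min: float
    t_mean: float
    t_max: float
    gradient: float  # max - min over cells, K
    transp_bin_edges: np.ndarray  # L m-2 h-1
    transp_density: np.ndarray  # area-weighted, integrates to 1
    cum_water: float  # kg


def field_statistics(
    result: SimulationResult, times: np.ndarray | list[float], bins: int = 20
) -> list[FieldStatistics]:
    """Per-snapshot field statistics at the requested times.

    Temperatures come from the stored cell fields; the transpiration-rate
    distribution is an area-weighted density over boundary faces in
    L m-2 h-1, normalised to unit integral (degenerate to a single unit-mass
    bin when the rate field is uniform).
    """
    if result.T_fields is None:
        raise ValueError("simulation was run without stored fields")
    out = []
    for t in np.atleast_1d(times):
        i = int(np.argmin(np.abs(result.times - t)))
        field_t = result.T_fields[i]
        rates = result.face_rates[i] * 3600.0  # L m-2 h-1
        lo, hi = float(rates.min()), float(rates.max())
        if hi - lo < 1e-15:
            edges = np.array([lo - 0.5e-6, lo + 0.5e-6])
            density = np.array([1.0 / (edges[1] - edges[0])])
        else:
            hist, edges = np.histogram(
                rates, bins=bins, range=(lo, hi), weights=result.face_area
            )
            density = hist / (hist.sum() * np.diff(edges))
        out.append(
            FieldStatistics(
                time=float(result.times[i]),
                t_min=float(field_t.min()),
                t_mean=float(field_t.mean()),
                t_max=float(field_t.max()),
                gradient=float(field_t.max() - field_t.min()),
                transp_bin_edges=edges,
                transp_density=density,
                cum_water=float(result.cum_water[i]),
            )
        )
    return out
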