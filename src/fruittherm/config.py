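"""Run configuration: schema, validation, defaults and object assembly.

A run is described by one YAML or JSON file with ``geometry``,
``properties``, ``environment`` and ``solver`` sections plus a global seed.
Unknown keys are rejected, defaults are filled in, and every defaulted
coefficient is echoed into the run metadata so a run can be re-executed
exactly.  The default property values describe a mature (M4) Cogshall
mango; development runs scale them through a schedule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .environment import WeatherSeries, synthesize_weather
from .geometry import Ellipsoid, FruitMesh, StoneGeometry, build_fruit_mesh
from .properties import SurfaceProperties, TissueProperties
from .solver import EnvironmentParams, SolverConfig

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "build_mesh",
    "build_tissues",
    "build_surfaces",
    "build_env_params",
    "build_solver_config",
    "build_weather",
    "run_simulation",
]


class ConfigError(ValueError):
    """Schema violation, reported with the offending field paths."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Strict):
    semi_axes: tuple[float, float, float] = (0.0625, 0.040, 0.0375)
    stone_ratios: tuple[float, float, float] = (0.85, 0.45, 0.30)
    peel_thickness: float = Field(0.001, gt=0.0)
    target_cells: int = Field(800, ge=800)
    sun_azimuth_deg: float = 0.0
    sun_elevation_deg: float = Field(45.0, ge=0.0, le=90.0)


class TissueConfig(_Strict):
    xw: float = Field(..., ge=0.0, le=1.0)
    Sg: float = Field(..., gt=0.0)


class SideConfig(_Strict):
    Gw: float = Field(..., ge=0.0)
    A_sw: float = Field(..., ge=0.0, le=1.0)


class PropertiesConfig(_Strict):
    conductivity_coeffs: tuple[float, float] = (0.148, 0.493)
    heat_capacity_coeffs: tuple[float, float] = (837.4, 3349.0)
    emissivity: float = Field(0.94, ge=0.0, le=1.0)
    pulp: TissueConfig = TissueConfig(xw=0.84, Sg=1056.0)
    peel: TissueConfig = TissueConfig(xw=0.72, Sg=1056.0)
    stone: TissueConfig = TissueConfig(xw=0.42, Sg=951.0)
    sunny: SideConfig = SideConfig(Gw=4.4e-4, A_sw=0.478)
    shaded: SideConfig = SideConfig(Gw=5.2e-4, A_sw=0.511)


class SyntheticWeatherConfig(_Strict):
    days: float = Field(1.0, gt=0.0)
    timestep_s: float = Field(3600.0, gt=0.0)
    t_min_c: float = 16.0
    t_max_c: float = 30.0
    rh_min: float = Field(40.0, ge=0.0, le=100.0)
    rh_max: float = Field(90.0, ge=0.0, le=100.0)
    peak_irradiance: float = Field(900.0, ge=0.0)
    wind: float = Field(1.5, ge=0.0)
    wind_noise: float = Field(0.0, ge=0.0)


class EnvironmentConfig(_Strict):
    diffuse_fraction: float = Field(0.15, ge=0.0, le=1.0)
    shaded_fraction: float = Field(0.20, ge=0.0, le=1.0)
    pressure: float = Field(101325.0, gt=0.0)
    weather_csv: str | None = None
    synthetic: SyntheticWeatherConfig = SyntheticWeatherConfig()


class SolverSection(_Strict):
    safety: float = Field(0.5, gt=0.0, le=1.0)
    output_cadence_s: float = Field(600.0, gt=0.0)
    store_fields: bool = True
    initial_temperature_c: float | None = None
    max_steps: int | None = None


class RunConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    properties: PropertiesConfig = PropertiesConfig()
    environment: EnvironmentConfig = EnvironmentConfig()
    solver: SolverSection = SolverSection()
    seed: int = 0
    output_dir: str = "runs"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return validate_config(data or {})


def validate_config(data: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        fields = sorted(
            {".".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()}
        )
        raise ConfigError(
            f"invalid configuration fields: {', '.join(fields)}\n{err}"
        ) from err


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# -- assembly -------------------------------------------------------------

def _sun_vectors(geo: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    """(split-plane normal, beam direction) from azimuth and elevation.

    Axis 0 is the fruit length axis (taken vertical); the sunny/shaded split
    is a vertical plane at the configured azimuth, while the beam direction
    additionally tilts by the solar elevation.
    """
    az = np.radians(geo.sun_azimuth_deg)
    el = np.radians(geo.sun_elevation_deg)
    split = np.array([0.0, np.cos(az), np.sin(az)])
    beam = np.array([np.sin(el), np.cos(el) * np.cos(az), np.cos(el) * np.sin(az)])
    return split, beam


def build_mesh(cfg: RunConfig) -> FruitMesh:
    geo = cfg.geometry
    fruit = Ellipsoid(*geo.semi_axes)
    stone = StoneGeometry.from_ratios(fruit, geo.stone_ratios)
    split, _ = _sun_vectors(geo)
    return build_fruit_mesh(
        fruit, stone, geo.peel_thickness, geo.target_cells, split
    )


def build_tissues(cfg: RunConfig) -> dict[str, TissueProperties]:
    p = cfg.properties
    return {
        name: TissueProperties.from_water_content(
            getattr(p, name).xw,
            getattr(p, name).Sg,
            p.conductivity_coeffs,
            p.heat_capacity_coeffs,
        )
        for name in ("pulp", "peel", "stone")
    }


def build_surfaces(cfg: RunConfig) -> dict[str, SurfaceProperties]:
    p = cfg.properties
    return {
        side: SurfaceProperties(
            A_sw=getattr(p, side).A_sw,
            emissivity=p.emissivity,
            Gw=getattr(p, side).Gw,
        )
        for side in ("sunny", "shaded")
    }


def build_env_params(cfg: RunConfig) -> EnvironmentParams:
    _, beam = _sun_vectors(cfg.geometry)
    return EnvironmentParams(
        diffuse_fraction=cfg.environment.diffuse_fraction,
        shaded_fraction=cfg.environment.shaded_fraction,
        sun_direction=beam,
    )


def build_solver_config(cfg: RunConfig) -> SolverConfig:
    s = cfg.solver
    t0 = s.initial_temperature_c
    return SolverConfig(
        safety=s.safety,
        output_cadence=s.output_cadence_s,
        max_steps=s.max_steps,
        initial_temperature=None if t0 is None else t0 + 273.15,
        store_fields=s.store_fields,
    )


def build_weather(cfg: RunConfig, seed: int | None = None) -> WeatherSeries:
    env = cfg.environment
    if env.weather_csv is not None:
        return WeatherSeries.from_csv(env.weather_csv)
    syn = env.synthetic
    return synthesize_weather(
        days=syn.days,
        timestep=syn.timestep_s,
        t_min_c=syn.t_min_c,
        t_max_c=syn.t_max_c,
        rh_min=syn.rh_min,
        rh_max=syn.rh_max,
        peak_irradiance=syn.peak_irradiance,
        wind=syn.wind,
        wind_noise=syn.wind_noise,
        seed=cfg.seed if seed is None else seed,
        pressure=env.pressure,
    )


def run_simulation(
    cfg: RunConfig,
    weather: WeatherSeries | None = None,
    schedule=None,
    dab_start: float | None = None,
):
    """Assemble all objects from the configuration and run the solver."""
    from .solver import simulate

    mesh = build_mesh(cfg)
    return simulate(
        mesh,
        build_tissues(cfg),
        build_surfaces(cfg),
        weather if weather is not None else build_weather(cfg),
        solver=build_solver_config(cfg),
        env=build_env_params(cfg),
        schedule=schedule,
        dab_start=dab_start,
    )
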