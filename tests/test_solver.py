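"""Explicit finite-volume update: conservation, stability, symmetry."""

import numpy as np
import pytest

from fruittherm.environment import WeatherRecord, WeatherSeries
from fruittherm.geometry import BOUNDARY, PULP, Ellipsoid, FruitMesh, StoneGeometry, grow_mesh
from fruittherm.properties import SurfaceProperties, TissueProperties
from fruittherm.solver import (
    EnvironmentParams,
    HeatBudgetSimulator,
    SolverConfig,
    StabilityError,
    ThermalState,
    advance_state,
    cfl_timestep,
    energy_audit,
    simulate,
)

T0C = 273.15
PULP_PROPS = TissueProperties(K=0.5, Cp=3600.0, Sg=1000.0)
NO_EXCHANGE = SurfaceProperties(A_sw=1.0, emissivity=0.0, Gw=0.0)


def tiny_mesh(n_cells: int, n_faces: int = 0) -> FruitMesh:
    """Hand-built 1- or 2-cell mesh for exact-arithmetic checks."""
    dx = 1e-3
    if n_cells == 1:
        centres = np.array([[0.5 * dx, 0.5 * dx, 0.5 * dx]])
    else:
        centres = np.array(
            [[-0.5 * dx, 0.5 * dx, 0.5 * dx], [0.5 * dx, 0.5 * dx, 0.5 * dx]]
        )
    labels = np.full(n_cells, PULP, np.int8)
    faces_per_cell = np.zeros(n_cells, int)
    if n_faces:
        face_cell = np.zeros(n_faces, int)
        face_normal = np.tile([[-1.0, 0.0, 0.0]], (n_faces, 1))
        face_side = np.ones(n_faces, bool)
        faces_per_cell[0] = n_faces
        labels[0] = BOUNDARY
    else:
        face_cell = np.zeros(0, int)
        face_normal = np.zeros((0, 3))
        face_side = np.zeros(0, bool)
    return FruitMesh(
        fruit0=Ellipsoid(dx, dx, dx),
        stone0=StoneGeometry(0.0, 0.0, 0.0),
        peel_thickness=1e-4,
        sun_normal=np.array([1.0, 0.0, 0.0]),
        dx0=dx,
        centres0=centres,
        labels=labels,
        faces_per_cell=faces_per_cell,
        face_cell=face_cell,
        face_normal=face_normal,
        face_side=face_side,
        area_factor=1.0,
    )


def uniform_tissues(tp=PULP_PROPS):
    return {"pulp": tp, "peel": tp, "stone": tp}


def both_sides(sp):
    return {"sunny": sp, "shaded": sp}


class TestUpdateIdentities:
    def test_two_cell_conduction_conserves_enthalpy(self):
        mesh = tiny_mesh(2)
        sim = HeatBudgetSimulator(
            mesh, uniform_tissues(), both_sides(NO_EXCHANGE),
            EnvironmentParams(fixed_h=0.0),
        )
        T = np.array([300.0, 310.0])
        h0 = sim.enthalpy(T)
        rec = WeatherRecord(time=0.0, Ta=295.0, RH=50.0, R_glob=0.0, u=0.0)
        dt = sim.cfl_dt(0.0, 0.5)
        water = np.zeros(0)
        for _ in range(200):
            sim.step(T, rec, dt, water)
        assert sim.enthalpy(T) == pytest.approx(h0, rel=1e-14)
        # both cells relax toward the common mean
        assert T[0] == pytest.approx(305.0, abs=1e-6)
        assert T[1] == pytest.approx(305.0, abs=1e-6)

    def test_single_cell_heat_to_temperature_identity(self):
        """dQ equal to Cp*V*Sg raises the cell temperature by exactly 1 K."""
        mesh = tiny_mesh(1, n_faces=1)
        tp = PULP_PROPS
        sp = SurfaceProperties(A_sw=0.0, emissivity=0.0, Gw=0.0)
        h = 5.0
        sim = HeatBudgetSimulator(
            mesh,
            uniform_tissues(tp),
            both_sides(sp),
            # beam along the face normal, no diffuse: the face sees R_glob
            EnvironmentParams(
                fixed_h=h, diffuse_fraction=0.0, sun_direction=np.array([-1.0, 0, 0])
            ),
        )
        Ta, Rg, T0 = 300.0, 400.0, 298.0
        S = float(sim.S_face[0])
        power = S * Rg + S * h * (Ta - T0)  # absorbed shortwave + convection
        cap = tp.Cp * mesh.cell_volume * tp.Sg
        dt = cap / power  # one step injects exactly Cp*V*Sg joules
        T = np.array([T0])
        rec = WeatherRecord(time=0.0, Ta=Ta, RH=50.0, R_glob=Rg, u=0.0)
        sim.step(T, rec, dt, np.zeros(1))
        assert T[0] - T0 == pytest.approx(1.0, rel=1e-12)

    def test_zero_fluxes_leave_state_unchanged(self):
        mesh = tiny_mesh(2)
        sim = HeatBudgetSimulator(
            mesh, uniform_tissues(), both_sides(NO_EXCHANGE),
            EnvironmentParams(fixed_h=0.0),
        )
        T = np.array([301.0, 301.0])  # no gradient, no boundary exchange
        rec = WeatherRecord(time=0.0, Ta=290.0, RH=50.0, R_glob=500.0, u=2.0)
        sim.step(T, rec, 0.5, np.zeros(0))
        assert np.array_equal(T, [301.0, 301.0])


class TestCflBound:
    def test_interior_bound_quadratic_in_spacing(self, sphere_mesh):
        sims = [
            HeatBudgetSimulator(m, uniform_tissues(), both_sides(NO_EXCHANGE))
            for m in (sphere_mesh, grow_mesh(sphere_mesh, 0.5))
        ]
        dts = [cfl_timestep(s, h_total=0.0, safety=0.5) for s in sims]
        assert dts[1] / dts[0] == pytest.approx(0.25, rel=1e-12)

    def test_interior_bound_inverse_in_conductivity(self, sphere_mesh):
        t1 = uniform_tissues()
        t2 = uniform_tissues(TissueProperties(K=1.0, Cp=3600.0, Sg=1000.0))
        dts = [
            cfl_timestep(
                HeatBudgetSimulator(sphere_mesh, t, both_sides(NO_EXCHANGE)),
                h_total=0.0,
            )
            for t in (t1, t2)
        ]
        assert dts[1] / dts[0] == pytest.approx(0.25 / 0.5, rel=1e-12)

    def test_stable_at_cfl_and_divergent_well_beyond(self, sphere_mesh):
        sim = HeatBudgetSimulator(
            sphere_mesh, uniform_tissues(), both_sides(NO_EXCHANGE),
            EnvironmentParams(fixed_h=5.0),
        )
        rec = WeatherRecord(time=0.0, Ta=T0C + 20, RH=50.0, R_glob=0.0, u=0.0)
        dt = sim.cfl_dt(sim.surface_exchange_coefficient(rec.Ta, 0.0), 1.0)
        T = np.full(sphere_mesh.n_cells, T0C + 16.0)
        for _ in range(3000):
            sim.step(T, rec, dt, np.zeros(sphere_mesh.n_faces))
        assert np.all(np.isfinite(T))
        assert T.min() >= T0C + 16.0 - 1e-6 and T.max() <= T0C + 20.0 + 1e-6

        T = np.full(sphere_mesh.n_cells, T0C + 16.0)
        for _ in range(2000):
            sim.step(T, rec, 10 * dt, np.zeros(sphere_mesh.n_faces))
            if not np.all(np.isfinite(T)) or np.abs(T).max() > 1e6:
                break
        assert not np.all(np.isfinite(T)) or np.abs(T).max() > 1e6

    def test_advance_state_enforces_the_bound(self, sphere_mesh):
        sim = HeatBudgetSimulator(
            sphere_mesh, uniform_tissues(), both_sides(NO_EXCHANGE),
            EnvironmentParams(fixed_h=5.0),
        )
        rec = WeatherRecord(time=0.0, Ta=T0C + 20, RH=50.0, R_glob=0.0, u=0.0)
        state = ThermalState(
            T=np.full(sphere_mesh.n_cells, T0C + 16.0),
            water_per_face=np.zeros(sphere_mesh.n_faces),
        )
        dt_crit = sim.cfl_dt(sim.surface_exchange_coefficient(rec.Ta, 0.0), 1.0)
        out = advance_state(state, sim, rec, 0.5 * dt_crit)
        assert out.t == pytest.approx(0.5 * dt_crit)
        assert state.t == 0.0  # input state untouched
        with pytest.raises(StabilityError):
            advance_state(state, sim, rec, 10 * dt_crit)


class TestConservationAndSymmetry:
    def test_pure_conduction_audit_and_maximum_principle(self, sphere_mesh, rng):
        """With a sealed boundary, a random field relaxes inside its own
        extrema and the audited residual vanishes to round-off."""
        weather = WeatherSeries(
            time=np.array([0.0, 3600.0]),
            Ta=np.full(2, T0C + 20),
            RH=np.full(2, 50.0),
            R_glob=np.zeros(2),
            u=np.zeros(2),
        )
        T_init = rng.uniform(T0C + 10, T0C + 30, sphere_mesh.n_cells)
        result = simulate(
            sphere_mesh,
            uniform_tissues(),
            both_sides(NO_EXCHANGE),
            weather,
            solver=SolverConfig(
                output_cadence=600.0, initial_temperature=T_init, warn_envelope=False
            ),
            env=EnvironmentParams(fixed_h=0.0),
        )
        assert energy_audit(result) < 1e-9
        assert result.T_min.min() >= T_init.min() - 1e-9
        assert result.T_max.max() <= T_init.max() + 1e-9
        # the field contracts toward its enthalpy-weighted mean
        assert result.T_max[-1] - result.T_min[-1] < T_init.max() - T_init.min()

    def test_symmetric_forcing_gives_mirror_symmetric_field(self, sphere_mesh):
        """All-diffuse, side-symmetric forcing must preserve the mesh's
        mirror symmetry across the sun plane to round-off."""
        sp = SurfaceProperties(A_sw=0.5, emissivity=0.94, Gw=5e-4)
        weather = WeatherSeries(
            time=np.array([0.0, 1800.0]),
            Ta=np.full(2, T0C + 25),
            RH=np.full(2, 60.0),
            R_glob=np.full(2, 600.0),
            u=np.full(2, 1.0),
        )
        result = simulate(
            sphere_mesh,
            uniform_tissues(),
            both_sides(sp),
            weather,
            solver=SolverConfig(output_cadence=1800.0, initial_temperature=T0C + 16),
            env=EnvironmentParams(
                fixed_h=5.0, diffuse_fraction=1.0, shaded_fraction=1.0
            ),
        )
        T = result.final_state.T
        key = {
            tuple(np.round(c / sphere_mesh.dx0, 3)): i
            for i, c in enumerate(sphere_mesh.centres0)
        }
        mirrored = np.array(
            [
                key[tuple(np.round(np.array([-c[0], c[1], c[2]]) / sphere_mesh.dx0, 3))]
                for c in sphere_mesh.centres0
            ]
        )
        assert np.max(np.abs(T - T[mirrored])) < 1e-9

    def test_transpired_mass_matches_latent_energy_bookkeeping(self, fruit_mesh):
        """Cumulative water equals the latent-energy integral divided by the
        vaporisation enthalpy, by construction of the per-face ledger."""
        sp = SurfaceProperties(A_sw=0.5, emissivity=0.94, Gw=5e-4)
        weather = WeatherSeries(
            time=np.array([0.0, 3600.0]),
            Ta=np.full(2, T0C + 30),
            RH=np.full(2, 40.0),
            R_glob=np.full(2, 500.0),
            u=np.full(2, 1.5),
        )
        result = simulate(
            fruit_mesh,
            uniform_tissues(),
            both_sides(sp),
            weather,
            solver=SolverConfig(output_cadence=600.0),
        )
        assert result.final_state.water_total > 0.0
        assert np.all(np.diff(result.cum_water) >= 0.0)
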