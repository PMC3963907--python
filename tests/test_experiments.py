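"""Analytic sphere series, goodness of fit, sensitivity and development."""

import numpy as np
import pytest

from fruittherm.config import RunConfig, build_weather
from fruittherm.experiments import (
    SphereCase,
    analytic_sphere_temperature,
    field_statistics,
    goodness_of_fit,
    run_development_experiment,
    sensitivity_analysis,
)
from fruittherm.schedules import default_mango_schedule

T0C = 273.15


class TestAnalyticSphere:
    def test_initial_condition_recovered(self):
        """At t = 0 the truncated series sums back to T0, and the truncation
        error shrinks as terms are added."""
        case = SphereCase()
        for r in (0.0, case.R / 2):
            err80 = abs(analytic_sphere_temperature(r, 0.0, case) - case.T0)
            err400 = abs(
                analytic_sphere_temperature(r, 0.0, case, n_terms=400) - case.T0
            )
            assert err80 < 5e-3
            assert err400 < err80

    def test_equilibrium_at_long_time(self):
        case = SphereCase()
        assert analytic_sphere_temperature(case.R, 1e6, case) == pytest.approx(
            case.Ta, abs=1e-9
        )

    def test_biot_number_of_reference_case(self):
        assert SphereCase().biot == pytest.approx(0.2)

    def test_small_biot_matches_lumped_capacitance(self):
        """For Bi << 1 the series collapses onto the lumped-reservoir
        exponential Ta + (T0-Ta)exp(-3 h t / (rho Cp R))."""
        case = SphereCase(h=0.05)  # Bi = 2e-3
        tau = case.lumped_time_constant
        t = np.linspace(0.0, 5 * tau, 40)
        series = analytic_sphere_temperature(0.0, t, case)
        lumped = case.Ta + (case.T0 - case.Ta) * np.exp(-t / tau)
        span = abs(case.T0 - case.Ta)
        assert np.max(np.abs(series - lumped)) < 1e-3 * span

    def test_monotone_warming_at_surface(self):
        case = SphereCase()
        t = np.linspace(0.0, 5 * case.lumped_time_constant, 50)
        temps = analytic_sphere_temperature(case.R, t, case)
        assert np.all(np.diff(temps) > 0)

    def test_out_of_domain_rejected(self):
        case = SphereCase()
        with pytest.raises(ValueError):
            analytic_sphere_temperature(case.R * 1.1, 10.0, case)


class TestGoodnessOfFit:
    def test_identical_series(self):
        y = np.array([1.0, 2.0, 3.0, 2.5])
        rmse, r2 = goodness_of_fit(y, y)
        assert rmse == 0.0 and r2 == pytest.approx(1.0)

    def test_constant_offset(self):
        y = np.array([1.0, 2.0, 3.0])
        rmse, r2 = goodness_of_fit(y, y + 0.7)
        assert rmse == pytest.approx(0.7)
        assert r2 == pytest.approx(1.0)

    def test_three_point_toy_case(self):
        rmse, _ = goodness_of_fit(np.array([1.0, 2, 3]), np.array([1.0, 2, 5]))
        assert rmse == pytest.approx(np.sqrt(4 / 3))

    def test_explained_variance_variant_penalises_offset(self):
        y = np.array([1.0, 2.0, 3.0])
        _, r2p = goodness_of_fit(y, y + 0.7, r2_method="pearson")
        _, r2e = goodness_of_fit(y, y + 0.7, r2_method="explained")
        assert r2p == pytest.approx(1.0) and r2e < 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.ones(3), np.ones(4))
        _, r2 = goodness_of_fit(np.ones(5), np.arange(5.0))
        assert np.isnan(r2)


class TestSensitivity:
    def test_gw_drives_transpiration_and_peel_thickness_is_inert(self):
        cfg = RunConfig()
        weather = build_weather(cfg, seed=11)
        table = sensitivity_analysis(
            cfg, parameters=("Gw", "peel_thickness"), weather=weather
        )
        gw = table[(table.parameter == "Gw") & table.output.str.startswith("transp")]
        # structural linearity, slightly damped by evaporative cooling
        assert np.all(gw.sc.to_numpy() > 0.90)
        assert np.all(gw.sc.to_numpy() < 1.02)
        pt = table[table.parameter == "peel_thickness"]
        assert np.all(np.abs(pt.sc.to_numpy()) < 0.02)
        # temperature falls when transpiration rises
        gwt = table[(table.parameter == "Gw") & table.output.str.startswith("T_max")]
        assert np.all(gwt.sc.to_numpy() < 0.0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_analysis(
                RunConfig(), parameters=("bogus",), weather=build_weather(RunConfig())
            )


class TestDevelopmentExperiment:
    def test_freezing_all_channels_equals_constant_m1_schedule(self):
        """Fixing every channel at M1 is the same run as a schedule that is
        constant at M1 throughout (starting meshes made identical)."""
        cfg = RunConfig()
        sched = default_mango_schedule()
        frozen = run_development_experiment(
            cfg, schedule=sched, variants={"all_fixed": {"size", "gw", "a_sw", "thermal"}},
            dab_end=63.0,
        )
        # a pre-frozen schedule has final size scale 1, so the configured
        # axes must already be the M1 axes for the meshes to coincide
        final_scale = sched.at(sched.span[1]).size_scale
        cfg2 = RunConfig()
        cfg2.geometry.semi_axes = tuple(
            a / final_scale for a in cfg.geometry.semi_axes
        )
        constant = run_development_experiment(
            cfg2,
            schedule=sched.fixed({"size", "gw", "a_sw", "thermal"}),
            variants={"all_fixed": set()},
            dab_end=63.0,
        )
        assert np.array_equal(frozen.to_numpy(), constant.to_numpy())

    def test_deterministic_given_schedule_and_weather(self):
        cfg = RunConfig()
        kw = dict(variants={"evolving": set()}, dab_end=62.0)
        a = run_development_experiment(cfg, **kw)
        b = run_development_experiment(cfg, **kw)
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestSchedules:
    def test_csv_round_trip(self, tmp_path):
        sched = default_mango_schedule()
        path = tmp_path / "schedule.csv"
        sched.to_csv(path)
        back = type(sched).from_csv(path)
        np.testing.assert_allclose(back.dab, sched.dab)
        np.testing.assert_allclose(back.size_scale, sched.size_scale)
        for t in sched.xw:
            np.testing.assert_allclose(back.xw[t], sched.xw[t])
        stage_a, stage_b = sched.at(75.0), back.at(75.0)
        assert stage_a.tissues["pulp"].K == pytest.approx(stage_b.tissues["pulp"].K)

    def test_interpolation_and_span(self):
        sched = default_mango_schedule()
        mid = sched.at(75.0)  # halfway M1 -> M2
        assert mid.size_scale == pytest.approx(1.125)
        assert mid.tissues["pulp"].xw == pytest.approx(0.875)
        with pytest.raises(ValueError):
            sched.at(50.0)
        with pytest.raises(ValueError):
            sched.fixed({"bogus"})

    def test_fixed_channels_are_constant(self):
        sched = default_mango_schedule().fixed({"size", "gw"})
        late = sched.at(130.0)
        assert late.size_scale == 1.0
        assert late.surfaces["sunny"].Gw == pytest.approx(5.4e-4)
        # unfrozen channels still evolve
        assert late.surfaces["sunny"].A_sw == pytest.approx(0.478)


class TestFieldStatistics:
    def test_uniform_start_and_normalised_distribution(self, fruit_mesh):
        from fruittherm.config import run_simulation

        cfg = RunConfig()
        cfg.environment.synthetic.days = 0.5
        res = run_simulation(cfg)
        stats = field_statistics(res, [0.0, 11.5 * 3600.0])
        first, noon = stats
        assert first.gradient == pytest.approx(0.0, abs=1e-12)  # uniform start
        assert noon.gradient > 0.5
        assert noon.t_min <= noon.t_mean <= noon.t_max
        integral = float(np.sum(noon.transp_density * np.diff(noon.transp_bin_edges)))
        assert integral == pytest.approx(1.0, rel=1e-9)
        assert noon.cum_water >= first.cum_water

    def test_requires_stored_fields(self):
        from fruittherm.config import run_simulation

        cfg = RunConfig()
        cfg.environment.synthetic.days = 0.1
        cfg.solver.store_fields = False
        res = run_simulation(cfg)
        with pytest.raises(ValueError):
            field_statistics(res, [0.0])
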