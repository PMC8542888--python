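"""Column geometry, the transport solver, the closed-form oracle and
inverse fitting."""

import numpy as np
import pytest

from sorbfate.exceptions import ConfigError, IdentifiabilityError, ValidationError
from sorbfate.transport import (
    ColumnLayer,
    ColumnTransportModel,
    FilterColumn,
    SoluteTransportParams,
    SolverSettings,
    analytic_breakthrough,
    field_filter,
    fit_column_params,
    half_breakthrough_time,
    layer_geometry,
    retardation,
    sand_control_filter,
    simulate_breakthrough,
)
from sorbfate.synth import ColumnTruth, generate_breakthrough

from conftest import make_homogeneous_column, seconds


class TestGeometry:
    def test_layer_depth_from_mass(self):
        layer = ColumnLayer("mix", mass=11.0, bulk_density=1.5, porosity=0.4)
        assert layer.depth(0.0908) == pytest.approx(11.0 / (1500.0 * 0.0908), rel=1e-12)

    def test_pore_velocity(self):
        column = field_filter(cross_section=0.0908)
        geometry = layer_geometry(column)
        # Q = 1 L/min through A = 0.0908 m^2 at theta = 0.4
        expected = (1.0 / 60000.0) / (0.0908 * 0.4)
        assert geometry["pore_velocity_m_s"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_residence_time_sums_to_pore_volume_over_flow(self):
        column = field_filter()
        geometry = layer_geometry(column)
        assert geometry["residence_min"].sum() == pytest.approx(
            column.pore_volume / column.flow_rate, rel=1e-9
        )

    def test_field_filter_composition(self):
        column = field_filter()
        assert [l.mass for l in column.layers] == [2.0, 11.0, 4.0, 7.0]
        mixed = column.layers[1]
        assert mixed.sand_fraction == pytest.approx(10.0 / 11.0)
        assert mixed.biochar_fraction == pytest.approx(1.0 / 11.0)
        control = sand_control_filter()
        assert control.layers[1].biochar_fraction == 0.0

    def test_invalid_layer_rejected(self):
        with pytest.raises(ConfigError):
            ColumnLayer("bad", mass=1.0, bulk_density=1.5, porosity=1.2)


class TestRetardation:
    def test_conservative_tracer(self):
        layer = ColumnLayer("sand", 1.0, 1.6, 0.4, sand_fraction=1.0)
        assert retardation(layer, SoluteTransportParams()) == 1.0

    def test_field_mixture_value(self):
        # theta=0.4, rho_b=1.6, f_s=10/11, f_bc=1/11, K_s=1.4, K_bc=12.2
        layer = ColumnLayer("mix", 11.0, 1.6, 0.4, sand_fraction=10 / 11, biochar_fraction=1 / 11)
        params = SoluteTransportParams(ks=1.4, kbc=12.2)
        assert params.kd(layer) == pytest.approx(2.3818, rel=1e-4)
        assert retardation(layer, params) == pytest.approx(10.527, rel=1e-4)

    def test_monotone_in_kbc(self):
        layer = ColumnLayer("mix", 1.0, 1.6, 0.4, biochar_fraction=0.5)
        r1 = retardation(layer, SoluteTransportParams(kbc=10.0))
        r2 = retardation(layer, SoluteTransportParams(kbc=20.0))
        assert r2 > r1


class TestAnalyticSolution:
    def test_long_time_limit_is_one(self):
        value = analytic_breakthrough(0.2, 1e-3, 1e-5, 2.0, 1e7)
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_time_is_zero(self):
        assert analytic_breakthrough(0.2, 1e-3, 1e-5, 2.0, 0.0) == 0.0
        assert analytic_breakthrough(0.2, 1e-3, 1e-5, 2.0, -5.0) == 0.0

    def test_half_breakthrough_near_retarded_arrival(self):
        """t_half lies near the retarded arrival R L / v; checked against an
        independent inline evaluation of the closed form."""
        from scipy.special import erfc as sp_erfc

        length, velocity, dispersion, r_factor = 0.2, 1e-3, 1e-5, 2.0

        def inline(t):
            denom = 2.0 * np.sqrt(dispersion * r_factor * t)
            z1 = (r_factor * length - velocity * t) / denom
            z2 = (r_factor * length + velocity * t) / denom
            return 0.5 * (
                sp_erfc(z1) + np.exp(velocity * length / dispersion) * sp_erfc(z2)
            )

        t_half = half_breakthrough_time(length, velocity, dispersion, r_factor)
        assert inline(t_half) == pytest.approx(0.5, abs=1e-9)
        # dispersion advances the median slightly ahead of R L / v
        assert t_half == pytest.approx(r_factor * length / velocity, rel=0.05)

    def test_monotone_in_time(self):
        t = np.linspace(1.0, 5000.0, 400)
        values = analytic_breakthrough(0.2, 1e-3, 1e-5, 2.0, t)
        assert np.all(np.diff(values) >= -1e-12)


class TestSolverAgainstOracle:
    @pytest.mark.parametrize("r_factor", [1.0, 2.0, 10.0])
    def test_equilibrium_solver_matches_closed_form(self, r_factor):
        """Observed at 0.2 m inside a padded column so the outlet boundary
        does not perturb the semi-infinite solution."""
        length, velocity, alpha = 0.2, 1e-3, 0.001
        column = make_homogeneous_column(
            depth=length, velocity=velocity, dispersivity=alpha,
            sand_fraction=1.0, pad_factor=2.0,
        )
        ks = (r_factor - 1.0) * 0.4 / 1.6
        volume = column.flow_rate * (3.0 * r_factor * length / velocity) / 60.0
        curve = simulate_breakthrough(
            column,
            SoluteTransportParams(ks=ks),
            duration_volume=volume,
            settings=SolverSettings(n_cells=400, inlet="concentration"),
            observation_depth=length,
        )
        exact = analytic_breakthrough(length, velocity, alpha * velocity, r_factor, seconds(curve, column))
        assert np.max(np.abs(curve.c_over_cin - exact)) <= 0.01

    def test_tracer_half_breakthrough_at_one_pore_volume(self):
        column = make_homogeneous_column(dispersivity=0.002, sand_fraction=1.0)
        volume = column.flow_rate * (3.0 * 0.2 / 1e-3) / 60.0
        curve = simulate_breakthrough(column, SoluteTransportParams(), duration_volume=volume)
        v_half = np.interp(0.5, curve.c_over_cin, curve.volumes)
        assert v_half == pytest.approx(column.pore_volume, rel=0.05)

    def test_mid_breakthrough_scales_linearly_with_r(self):
        column = make_homogeneous_column(dispersivity=0.002, biochar_fraction=1 / 11)
        arrivals = []
        for r_factor in (1.0, 2.0, 4.0):
            kbc = (r_factor - 1.0) * 0.4 / 1.6 * 11.0
            volume = column.flow_rate * (3.0 * r_factor * 0.2 / 1e-3) / 60.0
            curve = simulate_breakthrough(
                column, SoluteTransportParams(kbc=kbc), duration_volume=volume
            )
            arrivals.append(np.interp(0.5, curve.c_over_cin, curve.volumes))
        slopes = np.array(arrivals) / arrivals[0]
        assert slopes == pytest.approx([1.0, 2.0, 4.0], rel=0.05)

    def test_grid_refinement_convergence(self):
        column = make_homogeneous_column(dispersivity=0.002, sand_fraction=1.0)
        volume = column.flow_rate * (2.0 * 2.0 * 0.2 / 1e-3) / 60.0
        params = SoluteTransportParams(ks=0.25)  # R = 2
        coarse = simulate_breakthrough(
            column, params, duration_volume=volume,
            settings=SolverSettings(n_cells=300, courant=0.8),
        )
        fine = simulate_breakthrough(
            column, params, duration_volume=volume,
            settings=SolverSettings(n_cells=600, courant=0.4),
        )
        on_fine = np.interp(fine.volumes, coarse.volumes, coarse.c_over_cin)
        assert np.max(np.abs(on_fine - fine.c_over_cin)) < 0.002


class TestMassBalance:
    @pytest.mark.parametrize(
        "params",
        [
            SoluteTransportParams(),
            SoluteTransportParams(ks=1.4, kbc=12.2),
            SoluteTransportParams(ks=1.4, kbc=12.2, k=1e-3, mode="kinetic"),
        ],
    )
    def test_field_simulation_balances(self, params):
        curve = simulate_breakthrough(field_filter(), params, duration_volume=24.0)
        assert curve.mass_balance["relative_error"] < 0.005

    def test_balance_with_concentration_inlet(self):
        column = make_homogeneous_column(dispersivity=0.002, sand_fraction=1.0)
        volume = column.flow_rate * (600.0 / 60.0)
        curve = simulate_breakthrough(
            column, SoluteTransportParams(ks=0.25), duration_volume=volume,
            settings=SolverSettings(inlet="concentration"),
        )
        assert curve.mass_balance["relative_error"] < 0.005


class TestKineticLimits:
    def setup_method(self):
        self.column = make_homogeneous_column(
            depth=0.2, dispersivity=0.002, biochar_fraction=1 / 11
        )
        self.kbc = 0.25 * 11.0  # K_d = 0.25 -> R = 2
        self.volume = self.column.flow_rate * (3.0 * 2 * 0.2 / 1e-3) / 60.0
        self.settings = SolverSettings(n_cells=300, courant=0.5)

    def test_large_rate_reproduces_equilibrium_curve(self):
        equilibrium = simulate_breakthrough(
            self.column, SoluteTransportParams(kbc=self.kbc),
            duration_volume=self.volume, settings=self.settings,
        )
        k_large = 1e3 * 1e-3 / 0.2  # 10^3 * v / L
        kinetic = simulate_breakthrough(
            self.column, SoluteTransportParams(kbc=self.kbc, k=k_large, mode="kinetic"),
            duration_volume=self.volume, settings=self.settings,
        )
        assert np.max(np.abs(kinetic.c_over_cin - equilibrium.c_over_cin)) <= 0.01

    def test_zero_rate_reproduces_tracer(self):
        tracer = simulate_breakthrough(
            self.column, SoluteTransportParams(), duration_volume=self.volume,
            settings=self.settings,
        )
        frozen = simulate_breakthrough(
            self.column, SoluteTransportParams(kbc=self.kbc, k=0.0, mode="kinetic"),
            duration_volume=self.volume, settings=self.settings,
        )
        assert np.max(np.abs(frozen.c_over_cin - tracer.c_over_cin)) <= 1e-9

    def test_moderate_rate_shows_fronting_and_tailing(self):
        equilibrium = simulate_breakthrough(
            self.column, SoluteTransportParams(kbc=self.kbc),
            duration_volume=self.volume, settings=self.settings,
        )
        kinetic = simulate_breakthrough(
            self.column, SoluteTransportParams(kbc=self.kbc, k=2e-3, mode="kinetic"),
            duration_volume=self.volume, settings=self.settings,
        )

        def crossing(curve, level):
            return np.interp(level, curve.c_over_cin, curve.volumes)

        assert crossing(kinetic, 0.05) < crossing(equilibrium, 0.05)  # fronting
        assert crossing(kinetic, 0.95) > crossing(equilibrium, 0.95)  # tailing


class TestConditioning:
    def test_equilibrium_conditioning_sets_plateau_at_inverse_r(self):
        """After conditioning, resident water in the sorbing layer sits at
        C_in / R; the early effluent encodes the layer retardations."""
        curve = generate_breakthrough(
            ColumnTruth(params=SoluteTransportParams(ks=1.4, kbc=12.2), noise_cv=0.0)
        )
        # late samples approach the sand-biochar layer plateau 1/R = 1/10.527
        assert curve.c_over_cin[-1] == pytest.approx(1.0 / 10.527, rel=0.02)
        # the very first litre is dominated by non-sorbing bottom-gravel water
        assert curve.c_over_cin[0] > 0.9


class TestInverseFitting:
    def test_self_fit_is_a_fixed_point(self):
        """Fitting a simulated curve returns the generating parameters with
        a near-zero objective."""
        truth = SoluteTransportParams(ks=1.4, kbc=12.2)
        observed = generate_breakthrough(ColumnTruth(params=truth, noise_cv=0.0))
        result = fit_column_params(
            observed, field_filter(), free=("kbc",), fixed={"ks": 1.4}
        )
        assert result.rss < 1e-10
        assert result.params.kbc == pytest.approx(12.2, rel=0.02)

    def test_kinetic_truth_prefers_kinetic_model(self):
        truth = SoluteTransportParams(ks=1.4, kbc=12.2, k=1e-4, mode="kinetic")
        observed = generate_breakthrough(ColumnTruth(params=truth, noise_cv=0.0))
        column = field_filter()
        equilibrium_fit = fit_column_params(
            observed, column, free=("kbc",), mode="equilibrium", fixed={"ks": 1.4}
        )
        kinetic_fit = fit_column_params(
            observed, column, free=("kbc", "k"), mode="kinetic", fixed={"ks": 1.4}
        )
        assert kinetic_fit.rss < equilibrium_fit.rss

    def test_sand_only_column_rejects_free_kbc(self):
        observed = generate_breakthrough(
            ColumnTruth(column=sand_control_filter(), params=SoluteTransportParams(ks=1.4), noise_cv=0.0)
        )
        with pytest.raises(IdentifiabilityError):
            fit_column_params(observed, sand_control_filter(), free=("kbc",))

    def test_rate_not_free_in_equilibrium_mode(self):
        observed = generate_breakthrough(ColumnTruth(noise_cv=0.0))
        with pytest.raises(IdentifiabilityError):
            fit_column_params(observed, field_filter(), free=("k",), mode="equilibrium")

    def test_all_zero_curve_yields_lower_bound_result(self):
        observed = generate_breakthrough(ColumnTruth(c_in=0.0))
        result = fit_column_params(observed, field_filter(), free=("kbc",))
        assert result.lower_bound_only

    def test_too_few_points_rejected(self):
        observed = generate_breakthrough(
            ColumnTruth(noise_cv=0.0, sample_volumes=(1.0, 2.0, 3.0, 4.0))
        )
        with pytest.raises(ValidationError, match="at least 5"):
            ColumnTransportModel(observed, field_filter())

    def test_summary_reports_free_and_fixed(self):
        observed = generate_breakthrough(ColumnTruth(noise_cv=0.0))
        result = fit_column_params(observed, field_filter(), free=("kbc",), fixed={"ks": 1.4})
        text = result.summary()
        assert "kbc" in text and "fixed" in text and "free" in text
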