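import numpy as np
import pytest
from dataclasses import replace

from nodescale.geometry import spherocylinder
from nodescale.steady import (
    FitError,
    ModificationModelParams,
    SingularModelError,
    UniformModelParams,
    fit_scaling_prefactor,
    model1_closed_form,
    model1_direct_null,
    model1_numeric,
    model2_closed_form,
    model2_numeric,
    rho_cyt_at,
)


class TestCytoplasmicTrend:
    @pytest.mark.parametrize("L", [7.0, 10.5, 14.0])
    def test_zero_slope_is_constant(self, L):
        p = UniformModelParams(cyt_slope=0.0, rho_cyt_ref=2.5)
        assert rho_cyt_at(p, L) == 2.5

    @pytest.mark.parametrize("L, expect", [(14.0, 0.965), (7.0, 1.035)])
    def test_linear_trend(self, L, expect):
        p = UniformModelParams(cyt_slope=-0.01, L_ref=10.5, rho_cyt_ref=1.0)
        assert rho_cyt_at(p, L) == pytest.approx(expect)

    def test_clamped_non_negative(self):
        p = UniformModelParams(cyt_slope=-0.2, L_ref=5.0)
        assert rho_cyt_at(p, 100.0) == 0.0


class TestModelOne:
    def test_twofold_scaling_ratio(self, params1_const, geom_short, geom_long):
        """Doubling length roughly doubles nodal density at default rates."""
        r = (model1_closed_form(params1_const, geom_long).rho_nod
             / model1_closed_form(params1_const, geom_short).rho_nod)
        assert r == pytest.approx((0.005 + 3 / 7) / (0.005 + 3 / 14), rel=1e-12)
        assert r == pytest.approx(1.977, abs=0.001)

    def test_nu_zero_limit(self, geom_long):
        p = UniformModelParams(nu=0.0, cyt_slope=0.0)
        ss = model1_closed_form(p, geom_long)
        expect = 1.0 * (p.beta / p.eta) * geom_long.A_cor / geom_long.A_nod
        assert ss.rho_nod == pytest.approx(expect, rel=1e-12)

    def test_nodal_to_cortical_ratio_is_alpha_over_eta(self, params1_const):
        for L in (7.0, 10.0, 14.0):
            ss = model1_closed_form(params1_const, spherocylinder(L, 1.5, 3.0))
            assert ss.rho_nod / ss.rho_cor == pytest.approx(
                params1_const.alpha / params1_const.eta, rel=1e-12)
            assert ss.rho_nod / ss.rho_cor == pytest.approx(200.0, rel=1e-12)

    def test_singular_when_no_cortical_exit(self):
        with pytest.raises(SingularModelError):
            model1_closed_form(UniformModelParams(nu=0.0),
                               spherocylinder(10.0, 1.5, 0.0))

    @pytest.mark.parametrize("L", np.linspace(7, 14, 5))
    @pytest.mark.parametrize("nu", [0.0, 5e-3, 0.1])
    def test_numeric_matches_closed_form(self, L, nu):
        p = UniformModelParams(nu=nu)
        g = spherocylinder(L, 1.5, 3.0)
        a = model1_closed_form(p, g)
        b = model1_numeric(p, g)
        assert b.rho_nod == pytest.approx(a.rho_nod, rel=1e-10)
        assert b.rho_cor == pytest.approx(a.rho_cor, rel=1e-10)
        assert b.N_nod == pytest.approx(a.N_nod, rel=1e-10)

    def test_numeric_beta_zero(self, geom_long):
        ss = model1_numeric(UniformModelParams(beta=0.0), geom_long)
        assert ss.rho_cor == 0.0 and ss.rho_nod == 0.0

    def test_numeric_residuals_vanish(self, params1_const):
        g = spherocylinder(10.0, 1.5, 3.0)
        p = params1_const
        ss = model1_numeric(p, g)
        N_cyt = ss.rho_cyt * g.V
        influx = p.beta * (g.A_cor / g.V) * N_cyt
        r1 = influx - p.nu * ss.N_cor - p.alpha * (g.A_nod / g.A_cor) * ss.N_cor
        r2 = p.alpha * (g.A_nod / g.A_cor) * ss.N_cor - p.eta * ss.N_nod
        assert abs(r1) < 1e-12 * influx
        assert abs(r2) < 1e-12 * influx

    def test_monotone_increasing_in_length(self, params1_const):
        dens = [model1_closed_form(params1_const, spherocylinder(L, 1.5, 3.0)).rho_nod
                for L in np.linspace(7, 14, 15)]
        assert np.all(np.diff(dens) > 0)

    def test_area_proportional_in_low_nu_limit(self):
        """For nu/alpha -> 0 the nodal density scales exactly with A_cor."""
        p = UniformModelParams(nu=1e-12, cyt_slope=0.0)
        Ls = np.array([7.0, 9.0, 11.0, 14.0])
        dens = np.array([
            model1_closed_form(p, spherocylinder(L, 1.5, 3.0)).rho_nod for L in Ls
        ])
        areas = 2 * np.pi * 1.5 * Ls
        slope = np.polyfit(np.log(areas), np.log(dens), 1)[0]
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_beta_is_a_pure_prefactor(self, geom_long):
        p1 = UniformModelParams(cyt_slope=0.0)
        p2 = replace(p1, beta=2 * p1.beta)
        a, b = model1_closed_form(p1, geom_long), model1_closed_form(p2, geom_long)
        assert b.rho_cor == pytest.approx(2 * a.rho_cor, rel=1e-14)
        assert b.rho_nod == pytest.approx(2 * a.rho_nod, rel=1e-14)


class TestDirectNull:
    def test_independent_of_length(self, params1_const):
        a = model1_direct_null(params1_const, spherocylinder(7.0, 1.5, 3.0))
        b = model1_direct_null(params1_const, spherocylinder(14.0, 1.5, 3.0))
        assert b.rho_nod / a.rho_nod == pytest.approx(1.0, rel=1e-14)

    def test_zero_slope_versus_length(self, params1_const):
        Ls = np.linspace(7, 14, 8)
        dens = [model1_direct_null(params1_const, spherocylinder(L, 1.5, 3.0)).rho_nod
                for L in Ls]
        assert np.polyfit(Ls, dens, 1)[0] == pytest.approx(0.0, abs=1e-14)

    def test_formula(self, geom_long):
        p = UniformModelParams(beta=1.0, eta=5e-3, rho_cyt_ref=1.0, cyt_slope=0.0)
        assert model1_direct_null(p, geom_long).rho_nod == pytest.approx(200.0)
        p0 = replace(p, beta=0.0)
        assert model1_direct_null(p0, geom_long).rho_nod == 0.0


class TestModelTwo:
    def test_no_reversion_closed_form(self, geom_long):
        p = ModificationModelParams(mu=0.0)
        ss = model2_closed_form(p, geom_long)
        expect = (p.beta / p.eta) * (geom_long.A_cor / geom_long.A_nod) * 1.0
        assert ss.rho_nod == pytest.approx(expect, rel=1e-14)

    def test_strong_reversion_empties_nodes(self, geom_long):
        ss = model2_closed_form(ModificationModelParams(mu=1e12), geom_long)
        assert ss.rho_nod < 1e-9

    def test_default_ratio(self, geom_short, geom_long):
        """Reversion damps the twofold area scaling to about 1.82."""
        p = ModificationModelParams()
        r = (model2_closed_form(p, geom_long).rho_nod
             / model2_closed_form(p, geom_short).rho_nod)
        assert r == pytest.approx(1.824, abs=0.001)

    def test_continuous_mu_to_zero_limit(self, geom_long):
        a = model2_closed_form(ModificationModelParams(mu=0.0), geom_long)
        b = model2_closed_form(ModificationModelParams(mu=1e-9), geom_long)
        assert b.rho_nod == pytest.approx(a.rho_nod, rel=1e-6)

    def test_singular_without_band(self):
        with pytest.raises(SingularModelError):
            model2_closed_form(ModificationModelParams(), spherocylinder(10, 1.5, 0.0))

    def test_alpha_zero_cuts_flux_without_error(self, geom_long):
        ss = model2_closed_form(ModificationModelParams(alpha=0.0), geom_long)
        assert ss.rho_nod == 0.0

    @pytest.mark.parametrize("mu", np.logspace(-4, 0, 10))
    @pytest.mark.parametrize("L", np.linspace(7, 14, 10))
    def test_numeric_matches_closed_form_grid(self, mu, L):
        p = ModificationModelParams(mu=mu)
        g = spherocylinder(L, 1.5, 3.0)
        a = model2_closed_form(p, g)
        b = model2_numeric(p, g)
        assert b.rho_nod == pytest.approx(a.rho_nod, rel=1e-10)
        assert b.rho_cyt_mod == pytest.approx(a.rho_cyt_mod, rel=1e-10)

    def test_numeric_mass_flux_balance(self, geom_long):
        p = ModificationModelParams()
        g = geom_long
        ss = model2_numeric(p, g)
        N_mod = ss.rho_cyt_mod * g.V
        lhs = p.nu * ss.N_cor
        rhs = p.mu * N_mod + p.alpha * (g.A_nod / g.V) * N_mod
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_monotone_increasing_in_length(self):
        p = ModificationModelParams()
        dens = [model2_closed_form(p, spherocylinder(L, 1.5, 3.0)).rho_nod
                for L in np.linspace(7, 14, 15)]
        assert np.all(np.diff(dens) > 0)


class TestScalingFit:
    def test_prefactor_recovery(self, rng):
        p = UniformModelParams(cyt_slope=0.0)
        Ls = np.linspace(7, 14, 30)
        true = np.array([
            model1_closed_form(p, spherocylinder(L, 1.5, 3.0)).rho_nod for L in Ls
        ])
        data = 7.3 * true * (1 + 0.02 * rng.standard_normal(Ls.size))
        fit = fit_scaling_prefactor(Ls, data, model="model1", params=p)
        assert fit["prefactor"] == pytest.approx(7.3, rel=0.05)

    def test_noise_free_fit_is_perfect(self):
        p = UniformModelParams(cyt_slope=0.0)
        Ls = np.linspace(7, 14, 10)
        true = np.array([
            model1_closed_form(p, spherocylinder(L, 1.5, 3.0)).rho_nod for L in Ls
        ])
        fit = fit_scaling_prefactor(Ls, 3.1 * true, model="model1", params=p)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)
        assert fit["prefactor"] == pytest.approx(3.1, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_scaling_prefactor([10.0], [1.0])
        with pytest.raises(FitError):
            fit_scaling_prefactor([8, 10, 12], [0.0, 0.0, 0.0])
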