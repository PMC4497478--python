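import numpy as np
import pytest
from scipy.optimize import brentq

from vom.canopy import (BigLeafConfig, GasExchangeEnv, PhysiologyParams,
                        assimilation, canopy_fluxes, electron_transport,
                        jmax_at_temperature, lambda_from_suction, optimal_gs,
                        transpiration)
from vom.errors import DomainError, InvariantError

# the printed leaf-scale reference conditions
FIG4_ENV = dict(i_a=1000e-6, t_a=25.0, d_v=0.02, gamma_star=40.0)


def brute_force_gs(env, j_max25, lam, phys=None, n=1000, g_max=10.0):
    """Grid maximization of A_g - E_t/lambda (the independent oracle)."""
    phys = phys or PhysiologyParams()
    grid = np.linspace(0.0, g_max, n)
    best_g, best_f = 0.0, 0.0
    j_t = jmax_at_temperature(j_max25, env.t_a, phys.t_opt, phys.t_omega)
    # umol units throughout, PPFD converted from mol to umol
    j = electron_transport(env.i_a * 1e6, j_t, phys.alpha_q, phys.theta_j)
    for g in grid:
        a, _ = assimilation(g, env, j)
        f = a * 1e-6 - 1.6 * g * env.d_v / lam
        if f > best_f:
            best_f, best_g = f, g
    return best_g


class TestElectronTransport:
    def test_dark(self):
        assert electron_transport(0.0, 100.0) == 0.0

    def test_saturates_at_jmax(self):
        assert electron_transport(1e9, 100.0) == pytest.approx(100.0,
                                                               rel=1e-6)
        assert electron_transport(5e-4, 100.0) <= 100.0

    def test_half_saturation_of_rectangular_form(self):
        # at alpha_q * I_a = J_max the rectangular hyperbola gives J_max/2
        jmax = 120.0
        i_a = jmax / 0.3
        assert electron_transport(i_a, jmax, alpha_q=0.3) == \
            pytest.approx(jmax / 2.0, rel=1e-12)

    def test_curved_form_below_rectangular_and_saturating(self):
        jmax = 120.0
        for i_a in (10.0, 100.0, 400.0, 5000.0):
            j_curved = electron_transport(i_a, jmax, curvature=0.9)
            j_rect = electron_transport(i_a, jmax, curvature=0.0)
            assert 0.0 < j_curved <= jmax
            assert j_curved >= j_rect - 1e-12

    def test_concave_in_light(self):
        i = np.linspace(1.0, 3000.0, 200)
        j = np.array([electron_transport(x, 300.0) for x in i])
        assert np.all(np.diff(j) > 0)
        assert np.all(np.diff(j, 2) < 1e-12)

    def test_domain(self):
        with pytest.raises(DomainError):
            electron_transport(-1.0, 100.0)


class TestJmaxTemperature:
    def test_anchored_at_25(self):
        assert jmax_at_temperature(400.0, 25.0) == 400.0

    def test_cold_below_reference(self):
        assert jmax_at_temperature(400.0, 10.0) < 400.0

    def test_peak_at_configured_optimum(self):
        grid = np.linspace(-9.9, 59.9, 2000)
        vals = [jmax_at_temperature(400.0, t, t_opt=32.0) for t in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(32.0, abs=0.1)

    def test_positive_on_domain(self):
        assert all(jmax_at_temperature(400.0, t) > 0
                   for t in np.linspace(-9.9, 59.9, 50))

    def test_out_of_domain(self):
        with pytest.raises(DomainError):
            jmax_at_temperature(400.0, 75.0)


class TestAssimilation:
    ENV = GasExchangeEnv(**FIG4_ENV, c_a=380.0)

    def test_closed_stomata(self):
        a, ci = assimilation(0.0, self.ENV, 100.0)
        assert a == 0.0
        assert ci == 40.0

    def test_unrestricted_supply_limit(self):
        a, ci = assimilation(1e6, self.ENV, 100.0)
        assert ci == pytest.approx(380.0, rel=1e-4)
        assert a == pytest.approx(25.0 * (380 - 40) / (380 + 80), rel=1e-3)

    def test_printed_case_against_bracketing_oracle(self):
        g, j = 0.2, 100.0
        # independent root bracketing of g(Ca-Ci) = (J/4)(Ci-G*)/(Ci+2G*)
        f = lambda ci: g * (380.0 - ci) - (j / 4) * (ci - 40) / (ci + 80)
        ci_star = brentq(f, 40.0, 380.0, xtol=1e-12)
        a, ci = assimilation(g, self.ENV, j)
        assert ci == pytest.approx(ci_star, rel=1e-10)
        assert a == pytest.approx(g * (380.0 - ci_star), rel=1e-10)

    def test_ci_between_gamma_star_and_ca(self, rng):
        for _ in range(50):
            g = float(10.0 ** rng.uniform(-4, 1))
            j = float(rng.uniform(1.0, 600.0))
            a, ci = assimilation(g, self.ENV, j)
            assert 40.0 - 1e-9 <= ci <= 380.0 + 1e-9
            assert a >= 0.0

    def test_iwue_increasing_in_ca(self):
        # A/g = C_a - C_i grows with C_a at fixed g, J, Gamma*
        vals = []
        for ca in (300.0, 380.0, 500.0, 700.0):
            env = GasExchangeEnv(**FIG4_ENV, c_a=ca)
            a, _ = assimilation(0.15, env, 120.0)
            vals.append(a / 0.15)
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestTranspiration:
    def test_zero_deficit(self):
        assert transpiration(0.3, 0.0) == 0.0

    def test_linear_in_gs(self):
        assert transpiration(0.2, 0.01) == pytest.approx(
            2 * transpiration(0.1, 0.01), rel=1e-12)

    def test_printed_arithmetic(self):
        assert transpiration(0.1, 0.02) == pytest.approx(3.2e-3, rel=1e-12)


class TestLambdaFunction:
    def test_single_layer_linear(self):
        assert lambda_from_suction(50.0, 1.0, [2.5], 1) == pytest.approx(125.0)

    def test_zero_exponent_is_constant(self):
        assert lambda_from_suction(77.0, 0.0, [0.3, 5.0, 9.0], 3) == 77.0

    def test_three_layer_example(self):
        lam = lambda_from_suction(100.0, -0.5, [0.5, 1.0, 2.0], 3)
        assert lam == pytest.approx(100.0 * 3.5 ** -0.5, rel=1e-12)

    def test_rooting_depth_truncates_sum(self):
        lam = lambda_from_suction(100.0, -0.5, [0.5, 1.0, 2.0], 2)
        assert lam == pytest.approx(100.0 * 1.5 ** -0.5, rel=1e-12)

    def test_alt_grouping(self):
        lam = lambda_from_suction(10.0, 0.5, [1.0, 4.0], 2, alt_grouping=True)
        assert lam == pytest.approx(10.0 * (1.0 + 2.0), rel=1e-12)

    def test_zero_suction_negative_exponent_capped(self):
        lam = lambda_from_suction(100.0, -0.5, [0.0, 0.0], 2,
                                  lambda_max=5000.0)
        assert lam == 5000.0

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            lambda_from_suction(1.0, 1.0, [-0.1], 1)
        with pytest.raises(DomainError):
            lambda_from_suction(1.0, 1.0, [1.0], 2)


class TestOptimalGs:
    def test_water_too_costly_closes_stomata(self):
        env = GasExchangeEnv(**FIG4_ENV, c_a=380.0)
        res = optimal_gs(env, 250.0, lam=1.0)  # far below minimum slope
        assert res.g_s == 0.0
        assert res.a_g == 0.0

    def test_transpiration_nondecreasing_in_lambda(self):
        env = GasExchangeEnv(**FIG4_ENV, c_a=380.0)
        ets = [optimal_gs(env, 485.0, lam).e_t
               for lam in (100, 300, 1000, 3000, 10000)]
        assert all(b >= a - 1e-15 for a, b in zip(ets, ets[1:]))

    def test_matches_brute_force_under_printed_conditions(self):
        for lam in (150.0, 400.0, 1200.0, 3000.0):
            for ca in (317.0, 380.0):
                env = GasExchangeEnv(**FIG4_ENV, c_a=ca)
                res = optimal_gs(env, 485.0, lam)
                g_star = brute_force_gs(env, 485.0, lam)
                assert abs(res.g_s - g_star) <= 10.0 / 1000 + 1e-12

    def test_slope_equals_lambda_at_interior_optimum(self):
        env = GasExchangeEnv(**FIG4_ENV, c_a=380.0)
        phys = PhysiologyParams()
        for lam in (400.0, 1000.0, 2500.0):
            res = optimal_gs(env, 485.0, lam)
            assert 0 < res.g_s < phys.g_s_max
            # numerical slope dE/dA along g_s
            dg = 1e-6
            j_t = jmax_at_temperature(485.0, env.t_a)
            j = electron_transport(env.i_a * 1e6, j_t, phys.alpha_q,
                                   phys.theta_j)
            a1, _ = assimilation(res.g_s - dg, env, j)
            a2, _ = assimilation(res.g_s + dg, env, j)
            de = 1.6 * 2 * dg * env.d_v
            da = (a2 - a1) * 1e-6
            assert de / da == pytest.approx(lam, rel=1e-3)

    def test_supply_cap_respected_and_flagged(self):
        env = GasExchangeEnv(**FIG4_ENV, c_a=380.0)
        free = optimal_gs(env, 485.0, 2000.0)
        cap = free.e_t / 2.0
        res = optimal_gs(env, 485.0, 2000.0, supply_cap=cap)
        assert res.supply_limited
        assert res.e_t == pytest.approx(cap, rel=1e-12)
        assert res.g_s < free.g_s

    def test_dark_leaf_closed(self):
        env = GasExchangeEnv(i_a=0.0, t_a=20.0, d_v=0.01, c_a=380.0)
        res = optimal_gs(env, 485.0, 1000.0)
        assert res.g_s == 0.0 and res.e_t == 0.0

    def test_fig4_sign_structure(self):
        """High lambda + high capacity: eCO2 reduces E_t; low lambda + low
        capacity: eCO2 increases E_t."""
        def et(ca, jmax, lam):
            env = GasExchangeEnv(**FIG4_ENV, c_a=ca)
            return optimal_gs(env, jmax, lam).e_t
        for lam in (2000.0, 3000.0, 3670.0):
            assert et(380.0, 485.0, lam) < et(317.0, 485.0, lam)
        for lam in (207.0, 250.0, 287.0):
            assert et(380.0, 250.0, lam) > et(317.0, 250.0, lam)

    def test_invalid_lambda(self):
        env = GasExchangeEnv(**FIG4_ENV, c_a=380.0)
        with pytest.raises(DomainError):
            optimal_gs(env, 485.0, 0.0)


class TestCanopyFluxes:
    P = BigLeafConfig("perennial", 0.22, 250.0, 600.0, -0.4)
    S = BigLeafConfig("seasonal", 0.42, 250.0, 600.0, -0.4)
    ENV = GasExchangeEnv(**FIG4_ENV, c_a=317.0)

    def test_zero_cover_zero_fluxes(self):
        s0 = BigLeafConfig("seasonal", 0.0, 250.0, 600.0, -0.4)
        out = canopy_fluxes(self.P, s0, self.ENV, 500.0, 500.0)
        assert out.e_t_s == out.a_g_s == out.g_s_s == 0.0
        assert out.e_t_p > 0.0

    def test_ground_fluxes_scale_with_cover(self):
        p2 = BigLeafConfig("perennial", 0.44, 250.0, 600.0, -0.4)
        out1 = canopy_fluxes(self.P, self.S, self.ENV, 500.0, 500.0)
        out2 = canopy_fluxes(p2, self.S, self.ENV, 500.0, 500.0)
        assert out2.a_g_p == pytest.approx(2 * out1.a_g_p, rel=1e-12)
        assert out2.e_t_p == pytest.approx(2 * out1.e_t_p, rel=1e-12)

    def test_cover_constraint(self):
        # the printed site covers 0.22 + 0.42 are accepted
        canopy_fluxes(self.P, self.S, self.ENV, 500.0, 500.0)
        with pytest.raises(InvariantError):
            canopy_fluxes(
                BigLeafConfig("perennial", 0.7, 250.0, 600.0, -0.4),
                BigLeafConfig("seasonal", 0.5, 250.0, 600.0, -0.4),
                self.ENV, 500.0, 500.0)

    def test_totals_additive(self):
        out = canopy_fluxes(self.P, self.S, self.ENV, 500.0, 700.0)
        assert out.a_g_p == pytest.approx(
            out.perennial.a_g * self.P.m_a, rel=1e-12)
        assert out.e_t_s == pytest.approx(
            out.seasonal.e_t * self.S.m_a, rel=1e-12)
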