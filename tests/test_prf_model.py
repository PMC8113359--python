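"""Forward PRF model: quadrature accuracy, limits, symmetries, WF oracle."""

import math

import numpy as np
import pytest

from agesel import prf_model as pm
from agesel.errors import ConfigError

from conftest import brute_force_g_integral, brute_force_seg_integral


class TestGIntegral:
    def test_neutral_limits(self):
        assert pm.g_integral(0.0, 1) == pytest.approx(1.0, abs=1e-12)
        assert pm.g_integral(0.0, 3) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_matches_brute_force_quadrature(self):
        oracle = brute_force_g_integral(2.0, 1)
        assert pm.g_integral(2.0, 1) == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("ne_s,n", [(2.0, 5), (-2.0, 5), (50.0, 1), (-50.0, 20)])
    def test_vectorised_matches_scalar(self, ne_s, n):
        assert pm.g_integral_many(np.array([ne_s]), n)[0] == pytest.approx(
            pm.g_integral(ne_s, n), abs=1e-10
        )


class TestSegregatingIntegral:
    def test_matches_brute_force_quadrature(self):
        oracle = brute_force_seg_integral(8.0, 20)
        assert pm.segregating_integral(8.0, 20) == pytest.approx(oracle, abs=1e-7)

    @pytest.mark.parametrize("gamma", [-400.0, -8.0, -0.1, 0.1, 8.0, 400.0])
    @pytest.mark.parametrize("m", [2, 10, 40])
    def test_gauss_legendre_matches_adaptive(self, gamma, m):
        # the fast vectorised evaluator used at cohort scale must agree with
        # the adaptive scalar route to well below every downstream tolerance
        assert pm.segregating_integral_many(np.array([gamma]), m)[0] == pytest.approx(
            pm.segregating_integral(gamma, m), abs=1e-10, rel=1e-10
        )

    def test_series_branch_matches_quadrature_at_the_switch(self):
        # the near-neutral series and the quadrature route must agree where
        # the implementation switches between them
        for gamma in (1.00001e-6, 2e-6, -2e-6):
            series = pm.harmonic_number(9) + 0.5 * gamma * 9.0 / 11.0
            assert pm.segregating_integral(gamma, 10) == pytest.approx(
                series, abs=1e-10
            )


class TestExpectedPolySites:
    def test_synonymous_harmonic(self):
        p = pm.PRFParams(ne_s=0.0, alpha_m=0.5, mu_ratio=1.0, m=2, theta_S=1.0)
        assert pm.expected_poly_sites(p)[2] == pytest.approx(1.0, abs=1e-12)
        p10 = pm.PRFParams(ne_s=0.0, alpha_m=0.5, mu_ratio=1.0, m=10, theta_S=1.0)
        assert pm.expected_poly_sites(p10)[2] == pytest.approx(2.828968, abs=1e-6)

    def test_neutral_class_rates_match(self):
        # at s -> 0 the selected integrand reduces to the neutral one:
        # n_B/(alpha_m * muN) == n_S/muS
        p = pm.PRFParams(ne_s=0.0, alpha_m=0.3, mu_ratio=2.0, m=15, theta_S=3.0)
        n_b, n_d, n_s = pm.expected_poly_sites(p)
        assert n_b / (p.alpha_m * p.theta_S * p.mu_ratio) == pytest.approx(
            n_s / p.theta_S, abs=1e-8
        )

    def test_pn_ps_matches_brute_force(self):
        p = pm.PRFParams(ne_s=2.0, alpha_m=0.1, mu_ratio=1.0, m=20)
        h = pm.harmonic_number(19)
        oracle = (
            0.1 * brute_force_seg_integral(8.0, 20)
            + 0.9 * brute_force_seg_integral(-8.0, 20)
        ) / h
        assert pm.pn_ps_expected(p) == pytest.approx(oracle, abs=1e-7)


class TestFixedSites:
    def test_synonymous_fixed_count(self):
        p = pm.PRFParams(ne_s=0.0, alpha_m=0.5, mu_ratio=1.0, m=2, t_div=10.0)
        assert pm.expected_fixed_sites(p)[2] == pytest.approx(11.5, abs=1e-12)

    def test_neutral_limit(self):
        p = pm.PRFParams(ne_s=0.0, alpha_m=0.4, mu_ratio=2.0, m=5, t_div=7.0)
        f_b, f_d, f_s = pm.expected_fixed_sites(p)
        assert f_b + f_d == pytest.approx(2.0 * (7.0 + 1.0 / 5 + 1.0), abs=1e-8)

    def test_no_beneficial_class_when_alpha_zero(self):
        p = pm.PRFParams(ne_s=3.0, alpha_m=0.0, mu_ratio=1.0, m=10, t_div=5.0)
        assert pm.expected_fixed_sites(p)[0] == 0.0

    def test_large_t_div_converges_to_limit(self):
        p = pm.PRFParams(ne_s=1.5, alpha_m=0.2, mu_ratio=1.0, m=20, t_div=1e4)
        assert pm.dn_ds_expected(p) == pytest.approx(pm.dn_ds_limit(p), rel=1e-3)

    def test_convergence_is_monotone_in_t_div(self):
        lim = pm.dn_ds_ratio_limit(1.5, 0.2, 1.0)
        gaps = [
            abs(pm.dn_ds_ratio(1.5, 0.2, 1.0, 20, t) - lim)
            for t in (10.0, 100.0, 1000.0, 10000.0)
        ]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestDnDsLimit:
    def test_neutral_value(self):
        assert pm.dn_ds_ratio_limit(0.0, 0.5, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_pure_deleterious_closed_form(self):
        assert pm.dn_ds_ratio_limit(1.0, 0.0, 1.0) == pytest.approx(
            1.0 / (math.e - 1.0), abs=1e-12
        )

    def test_pure_beneficial_closed_form(self):
        assert pm.dn_ds_ratio_limit(1.0, 1.0, 1.0) == pytest.approx(
            1.0 / (1.0 - math.exp(-1.0)), abs=1e-12
        )

    def test_monotone_in_selection_strength(self):
        xs = np.linspace(0.05, 10.0, 40)
        del_vals = [pm.dn_ds_ratio_limit(x, 0.0, 1.0) for x in xs]
        ben_vals = [pm.dn_ds_ratio_limit(x, 1.0, 1.0) for x in xs]
        assert all(a > b for a, b in zip(del_vals, del_vals[1:]))
        assert all(v < 1.0 for v in del_vals)
        assert all(a < b for a, b in zip(ben_vals, ben_vals[1:]))
        assert all(v > 1.0 for v in ben_vals)


class TestScaleCancellation:
    @pytest.mark.parametrize("theta", [1e-3, 1.0, 1e3])
    def test_ratios_do_not_depend_on_theta(self, theta):
        base = pm.PRFParams(ne_s=1.0, alpha_m=0.3, mu_ratio=2.0, m=12,
                            t_div=5.0, theta_S=1.0)
        other = pm.PRFParams(ne_s=1.0, alpha_m=0.3, mu_ratio=2.0, m=12,
                             t_div=5.0, theta_S=theta)
        assert pm.pn_ps_expected(base) == pytest.approx(
            pm.pn_ps_expected(other), rel=1e-12
        )
        assert pm.dn_ds_expected(base) == pytest.approx(
            pm.dn_ds_expected(other), rel=1e-12
        )


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"ne_s": -1.0},
            {"alpha_m": 1.5},
            {"mu_ratio": 0.0},
            {"m": 1},
            {"theta_S": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        base = dict(ne_s=1.0, alpha_m=0.5, mu_ratio=1.0, m=10)
        with pytest.raises(ConfigError):
            pm.PRFParams(**{**base, **kw})


class TestWrightFisherOracle:
    def test_neutral_ratio(self):
        r = pm.wf_oracle(0.0, 0.5, 0.02, 0.01, pop_size=50, m=10,
                         generations=30_000, seed=1)
        # muN/muS = 2; neutral segregating ratio must match within 3 SE
        assert abs(r.ratio_NS - 2.0) < 3.0 * r.ratio_NS_se

    def test_neutral_fixation_rate(self):
        # neutral substitutions accumulate at the mutation rate: expected
        # fixations = mu_total * generations regardless of population size
        r = pm.wf_oracle(0.0, 0.5, 0.02, 0.04, pop_size=50, m=10,
                         generations=30_000, seed=2)
        for cls, mu in (("S", 0.04), ("B", 0.01), ("D", 0.01)):
            expected = mu * r.generations
            se = math.sqrt(expected)
            assert abs(r.fixations[cls] - expected) < 4.0 * se

    def test_refuses_large_population(self):
        with pytest.raises(ConfigError):
            pm.wf_oracle(0.0, 0.5, 0.01, 0.01, pop_size=500, m=10,
                         generations=1000, seed=0)

    def test_refuses_high_mutation_rate(self):
        with pytest.raises(ConfigError):
            pm.wf_oracle(0.0, 0.5, 2.0, 0.01, pop_size=50, m=10,
                         generations=1000, seed=0)
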