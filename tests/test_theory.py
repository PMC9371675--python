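"""Critical population sizes, minimal gRNA counts, sigmoid fitting."""

import itertools
import math

import numpy as np
import pytest

from multidrive import (
    DriveParams,
    TheoryConstants,
    amplification_ratio,
    contour_N,
    critical_N_combined,
    critical_N_denovo,
    critical_N_nhej,
    critical_N_standing,
    fit_sigmoid,
    implied_gamma_n,
    min_m_nhej,
    min_m_standing,
    p_resistance,
)
from multidrive.theory import _min_m_brute


@pytest.fixture
def consts():
    return TheoryConstants()


def params(m=1, **kw):
    kw.setdefault("K", 1000)
    return DriveParams(m=m, **kw)


class TestSigmoid:
    def test_anchor_points(self):
        assert p_resistance(0.0, 1e4) == 0.0
        assert p_resistance(1e4, 1e4) == pytest.approx(1 - math.exp(-1))
        assert p_resistance(1e4 * math.log(20), 1e4) == pytest.approx(0.95)

    def test_contour_inverts_sigmoid(self):
        n_star = 3.3e5
        for p in (0.01, 0.05, 1 - math.exp(-1), 0.99):
            assert p_resistance(contour_N(p, n_star), n_star) == pytest.approx(p)
        assert contour_N(0.05, 1.0) == pytest.approx(math.log(20 / 19))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            p_resistance(10, 0.0)
        with pytest.raises(ValueError):
            contour_N(1.0, 1e4)


class TestCriticalSizes:
    def test_nhej_values(self, consts):
        assert critical_N_nhej(params(beta=1.0), consts) == pytest.approx(26.32, rel=1e-3)
        # population-level rate at N = N*_n is 1/(2 gamma_n) = 2.5 per generation
        for m in (1, 2, 3):
            p = params(m=m, beta=0.01)
            rate = (p.epsilon * p.nu * p.beta) ** m
            assert 2 * critical_N_nhej(p, consts) * rate == pytest.approx(2.5)
        # adding a gRNA multiplies N* by 1/(eps nu beta)
        r = critical_N_nhej(params(m=2, beta=0.01), consts) / critical_N_nhej(
            params(m=1, beta=0.01), consts
        )
        assert r == pytest.approx(1 / (0.95 * 0.05 * 0.01))
        assert critical_N_nhej(params(beta=0.0), consts) == math.inf

    def test_denovo_population_rates(self, consts):
        for m, expected in [(1, 0.658), (2, 0.083), (3, 0.009)]:
            p = params(m=m, xi=1.0)
            rate = (p.xi * p.mu) ** m
            assert 2 * critical_N_denovo(p, consts) * rate == pytest.approx(
                expected, rel=0.02
            )
        assert critical_N_denovo(params(xi=0.0), consts) == math.inf

    def test_gamma_m_extrapolation_consistent_with_table(self, consts):
        for m, table_value in consts.gamma_m.items():
            extrapolated = consts.s_b_denovo * consts.tau**m
            assert extrapolated == pytest.approx(table_value, rel=0.1)

    def test_standing_m1_is_single_site_form(self, consts):
        p = params(sigma=1e-3, xi=1.0)
        expected = 1 / (4 * p.xi * p.mu * math.log(1 + consts.s_b / p.sigma))
        assert critical_N_standing(p, consts) == pytest.approx(expected)

    def test_standing_m2_value(self, consts):
        p = params(m=2, sigma=1e-4, xi=1.0)
        assert critical_N_standing(p, consts) == pytest.approx(2.7e8, rel=0.02)

    def test_standing_scales_with_sigma_power(self, consts):
        """N*_s ~ sigma^(m-1) up to the logarithmic factor."""
        m = 3
        lo, hi = 1e-5, 1e-3
        ratio = critical_N_standing(params(m=m, sigma=hi), consts) / critical_N_standing(
            params(m=m, sigma=lo), consts
        )
        log_factor = math.log(1 + 0.5 / (m * lo)) / math.log(1 + 0.5 / (m * hi))
        assert ratio == pytest.approx((hi / lo) ** (m - 1) * log_factor, rel=1e-9)

    def test_sigma_zero_rejected(self, consts):
        with pytest.raises(ValueError):
            critical_N_standing(params(sigma=0.0), consts)

    def test_combined_harmonic(self, consts):
        p = params(m=1, beta=1e-4, sigma=0.01, xi=1.0)
        n = critical_N_combined(p, consts)
        n_n = critical_N_nhej(p, consts)
        n_s = critical_N_standing(p, consts)
        assert n == pytest.approx(1 / (1 / n_n + 1 / n_s))
        assert n <= min(n_n, n_s)
        # beta -> 0 limit reduces to the standing-variation critical size
        assert critical_N_combined(p.with_(beta=0.0), consts) == pytest.approx(n_s)
        # p=0.05 contour near 1e4 for this corner (printed-table cross-check)
        assert contour_N(0.05, n) == pytest.approx(1.1e4, rel=0.15)


class TestMinimalM:
    def test_nhej_published_values(self, consts):
        assert min_m_nhej(1e6, 0.05, params(beta=1.0), consts) == 6
        assert min_m_nhej(1e6, 0.05, params(beta=0.01), consts) == 3
        for beta, expected in [(1.0, 8), (0.01, 4), (1e-4, 2)]:
            assert min_m_nhej(1e9, 0.05, params(beta=beta), consts) == expected

    def test_standing_published_values(self, consts):
        p = params(sigma=1e-6, xi=1.0)
        assert min_m_standing(1e6, 0.05, p, consts) == 4
        assert min_m_standing(1e6, 0.05, p.with_(sigma=1e-4), consts) == 2
        for sigma, expected in [(1e-6, 7), (1e-4, 3), (1e-2, 2)]:
            assert min_m_standing(1e9, 0.05, p.with_(sigma=sigma), consts) == expected

    def test_lambert_agrees_with_brute_force_on_grid(self, consts):
        """Closed forms match brute-force inversion over the parameter grid."""
        for N, beta in itertools.product([1e3, 1e6, 1e9, 1e12], [1.0, 1e-2, 1e-4]):
            p = params(beta=beta)
            brute = _min_m_brute(
                N, 0.05, lambda m: critical_N_nhej(p.with_(m=m), consts)
            )
            assert min_m_nhej(N, 0.05, p, consts) == brute
        for N, sigma, xi in itertools.product(
            [1e3, 1e6, 1e9, 1e12], [1e-6, 1e-4, 1e-2], [1.0, 0.01]
        ):
            p = params(sigma=sigma, xi=xi)
            brute = min_m_standing(N, 0.05, p, consts, method="brute")
            lam = min_m_standing(N, 0.05, p, consts, method="lambert")
            assert abs(lam - brute) <= 1, (N, sigma, xi)

    def test_lambert_out_of_domain_falls_back(self, consts):
        # at small N the W_{-1} argument drops below -1/e: fall back to brute
        p = params(sigma=1e-4, xi=1.0)
        with pytest.warns(UserWarning):
            lam = min_m_standing(100.0, 0.05, p, consts, method="lambert")
        assert lam == min_m_standing(100.0, 0.05, p, consts, method="brute")

    def test_no_finite_m_when_mutant_classes_not_rare(self, consts):
        """gamma*xi*mu >= sigma: extra gRNAs cannot raise the standing N*."""
        p = params(sigma=1e-8, xi=1.0)
        with pytest.raises(RuntimeError):
            min_m_standing(1e6, 0.05, p, consts, method="brute")


class TestAmplification:
    def test_published_ratios(self, consts):
        for m, expected in [(1, 5), (2, 217), (3, 6266)]:
            assert amplification_ratio(m, 0.01, consts) == pytest.approx(expected, rel=0.05)
        for m, expected in [(1, 11), (2, 5.2e4), (3, 1.6e8)]:
            assert amplification_ratio(m, 1e-4, consts) == pytest.approx(expected, rel=0.05)

    def test_m1_has_no_sigma_power(self, consts):
        sigma = 3e-3
        expected = math.log(1 + consts.s_b / sigma) / consts.gamma_m_for(1)
        assert amplification_ratio(1, sigma, consts) == pytest.approx(expected)

    def test_monotone_decreasing_in_sigma(self, consts):
        for m in (2, 3):
            values = [amplification_ratio(m, s, consts) for s in (1e-6, 1e-4, 1e-2)]
            assert values[0] > values[1] > values[2]


class TestFitSigmoid:
    def test_single_point_exact_inversion(self):
        n_reps = 100_000
        k = round(n_reps * (1 - math.exp(-1)))
        fit = fit_sigmoid([5000.0], [k], [n_reps])
        assert fit.N_star == pytest.approx(5000.0, rel=1e-3)

    def test_parameter_recovery(self, rng):
        """Synthetic outcomes from the sigmoid recover N* within 10%."""
        true_nstar = 1e5
        N = np.logspace(4, 6, 8)
        n_reps = np.full(8, 500)
        k = rng.binomial(n_reps, p_resistance(N, true_nstar))
        fit = fit_sigmoid(N, k, n_reps)
        assert fit.N_star == pytest.approx(true_nstar, rel=0.10)
        assert fit.ci_low < true_nstar < fit.ci_high

    def test_boundary_outcomes_flagged(self):
        fit = fit_sigmoid([100.0, 200.0], [0, 0], [50, 50])
        assert fit.boundary == "upper"
        fit = fit_sigmoid([100.0, 200.0], [50, 50], [50, 50])
        assert fit.boundary == "lower"

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([], [], [])
        with pytest.raises(ValueError):
            fit_sigmoid([100.0], [10], [5])

    def test_implied_gamma_round_trip(self, consts):
        p = params(m=2, beta=0.01)
        n_star = critical_N_nhej(p, consts)
        assert implied_gamma_n(n_star, p) == pytest.approx(consts.gamma_n)
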