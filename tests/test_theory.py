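import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rwmtune as rt
from rwmtune import InformationMetric


class TestAcceptanceMatched:
    def test_zero_step_always_accepted(self):
        assert rt.acceptance_matched(0.0, 5).value == 1.0

    @pytest.mark.parametrize("ell", [0.5, 1.5, 2.42, 4.0])
    def test_d1_closed_form(self, ell):
        # for a 1-D Gaussian target: 1 - (2/pi) arctan(ell/2)
        expected = 1.0 - (2.0 / np.pi) * np.arctan(ell / 2.0)
        assert rt.acceptance_matched(ell, 1).value == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("ell", [0.5, 2.42, 4.0])
    def test_d2_closed_form(self, ell):
        a = ell / (2.0 * np.sqrt(2.0))
        expected = 1.0 - a / np.sqrt(1.0 + a * a)
        assert rt.acceptance_matched(ell, 2).value == pytest.approx(expected, abs=1e-9)

    def test_huge_dimension_reaches_0234(self):
        val = rt.acceptance_matched(2.38, 10**6).value
        assert val == pytest.approx(0.2340, abs=5e-4)

    @pytest.mark.parametrize("ell,d", [(2.42, 1), (2.42, 2), (2.40, 10), (2.38, 50)])
    def test_student_t_identity_vs_monte_carlo(self, ell, d):
        # E[Phi(-a chi_d)] with a = ell/(2 sqrt(d)) equals F_t_d(-ell/2)
        mc = rt.acceptance_matched(ell, d, method="monte_carlo", seed=101)
        exact = 2.0 * stats.t.cdf(-ell / 2.0, df=d)
        assert abs(mc.value - exact) < 3.0 * mc.std_error

    def test_monte_carlo_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            rt.acceptance_matched(2.4, 3, method="monte_carlo")

    @pytest.mark.parametrize("bad", [(-1.0, 3), (2.0, 0), (2.0, -2)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            rt.acceptance_matched(*bad)


class TestEsjdMatched:
    def test_zero_step_gives_zero(self):
        assert rt.esjd_matched(0.0, 7).value == 0.0

    @pytest.mark.parametrize("ell,d", [(1.0, 1), (2.42, 2), (2.39, 9), (3.5, 20)])
    def test_quadrature_within_3se_of_monte_carlo(self, ell, d):
        quad = rt.esjd_matched(ell, d)
        mc = rt.esjd_matched(ell, d, method="monte_carlo", seed=7)
        assert abs(quad.value - mc.value) < 3.0 * mc.std_error

    def test_d1_argmax_at_grid_resolution(self):
        grid = np.round(np.arange(2.0, 3.0, 0.01), 10)
        vals = [rt.esjd_matched(l, 1).value for l in grid]
        ell_hat = grid[int(np.argmax(vals))]
        assert abs(ell_hat - 2.42) <= 0.011  # printed guideline value, flat optimum


class TestIdentityProposalFormulas:
    def test_identity_metric_coincides_with_matched(self):
        d = 4
        info = InformationMetric.identity(d)
        lam = 2.3 / np.sqrt(d)
        a_id = rt.acceptance_identity(lam, info, method="quadrature")
        assert a_id.value == pytest.approx(rt.acceptance_matched(2.3, d).value, abs=1e-9)
        e_id = rt.esjd_identity(lam, info, method="quadrature")
        assert e_id.value == pytest.approx(rt.esjd_matched(2.3, d).value, abs=1e-9)

    def test_scalar_metric_reduces_to_matched(self):
        info = InformationMetric.from_matrix([[4.0]])
        got = rt.acceptance_identity(1.0, info, method="quadrature")
        assert got.value == pytest.approx(rt.acceptance_matched(2.0, 1).value, abs=1e-9)

    def test_zero_step_limits(self):
        info = InformationMetric.identity(3)
        assert rt.acceptance_identity(0.0, info).value == 1.0
        assert rt.esjd_identity(0.0, info).value == 0.0

    def test_general_metric_mc_agrees_with_scalar_quadrature(self):
        # 2x2 scalar metric: the MC path must agree with the exact reduction
        info = InformationMetric.from_matrix(2.5 * np.eye(2))
        mc = rt.acceptance_identity(1.1, info, method="monte_carlo", seed=5)
        exact = rt.acceptance_identity(1.1, info, method="quadrature")
        assert abs(mc.value - exact.value) < 3.0 * mc.std_error
        mc_e = rt.esjd_identity(1.1, info, method="monte_carlo", seed=5)
        exact_e = rt.esjd_identity(1.1, info, method="quadrature")
        assert abs(mc_e.value - exact_e.value) < 3.0 * mc_e.std_error

    def test_general_metric_quadrature_raises(self, ar1_metric_d9):
        with pytest.raises(ValueError, match="monte_carlo"):
            rt.acceptance_identity(0.8, ar1_metric_d9, method="quadrature")


class TestAsymptotics:
    def test_limits_at_zero(self):
        assert rt.asymptotic_acceptance(0.0) == 1.0
        assert rt.asymptotic_esjd(0.0) == 0.0

    def test_value_at_guideline_point(self):
        # 2 * 2.38^2 * Phi(-1.19), evaluated independently via the normal CDF
        assert rt.asymptotic_esjd(2.38) == pytest.approx(1.3258, abs=5e-4)
        assert rt.asymptotic_acceptance(2.38) == pytest.approx(0.234, abs=5e-4)

    def test_finite_d_converges_to_limit(self):
        d = 10**4
        assert abs(rt.acceptance_matched(2.38, d).value - rt.asymptotic_acceptance(2.38)) < 0.002
        assert abs(rt.esjd_matched(2.38, d).value - rt.asymptotic_esjd(2.38)) < 0.002

    def test_L_prime_one_recovers_plain_limit(self):
        for ell in (0.5, 2.38, 5.0):
            assert rt.esjd_limit_with_L(ell, 1.0) == pytest.approx(rt.asymptotic_esjd(ell))

    def test_L_prime_rescales_argmax(self):
        grid = np.round(np.arange(0.5, 4.0, 0.01), 10)
        hat1 = grid[np.argmax(rt.esjd_limit_with_L(grid, 1.0))]
        hat4 = grid[np.argmax(rt.esjd_limit_with_L(grid, 4.0))]
        assert hat1 == pytest.approx(2.38, abs=0.005)
        assert hat4 == pytest.approx(1.19, abs=0.005)

    def test_L_prime_validation(self):
        with pytest.raises(ValueError):
            rt.esjd_limit_with_L(2.0, 0.0)


class TestAR1LPrime:
    def test_uncorrelated_is_one(self):
        assert rt.ar1_L_prime(0.0) == 1.0

    def test_half_is_five_thirds(self):
        assert rt.ar1_L_prime(0.5) == pytest.approx(5.0 / 3.0)

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_matches_numeric_trace(self, rho):
        # finite-d trace: the two boundary rows of the tridiagonal inverse
        # each fall short of the interior diagonal by rho^2/(1-rho^2)
        d = 1000
        sigma = rt.ar1_covariance(rho, d)
        numeric = np.trace(np.linalg.inv(sigma)) / d
        limit = rt.ar1_L_prime(rho)
        boundary = 2.0 * rho**2 / ((1.0 - rho**2) * d)
        assert numeric == pytest.approx(limit - boundary, abs=1e-9)
        assert abs(limit - numeric) < 5.0 / d

    def test_domain(self):
        with pytest.raises(ValueError):
            rt.ar1_L_prime(1.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(ell=st.floats(0.1, 8.0), d=st.integers(1, 40))
def test_acceptance_in_unit_interval_and_esjd_nonnegative(ell, d):
    acc = rt.acceptance_matched(ell, d).value
    assert 0.0 <= acc <= 1.0
    assert rt.esjd_matched(ell, d).value >= 0.0


@settings(deadline=None, derandomize=True, max_examples=10)
@given(d=st.integers(1, 30))
def test_acceptance_strictly_decreasing_in_ell(d):
    grid = np.array([0.5, 1.0, 2.0, 3.0, 5.0])
    vals = [rt.acceptance_matched(l, d).value for l in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_efficiency_value_invariants():
    with pytest.raises(ValueError):
        rt.EfficiencyValue(-0.1)
    with pytest.raises(ValueError):
        rt.EfficiencyValue(0.5, std_error=0.01, method="quadrature")
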