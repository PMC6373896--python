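"""Compensating income variation: transform, delta method, monetization,
pooling and consumption equivalents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affectprice.pricing import (
    CIVResult,
    CoefPair,
    IncomeTaxTable,
    civ_fraction,
    civ_gradient,
    civ_result,
    civ_se,
    convert_consumption_equivalents,
    monetize_civ,
    pool_civ,
    round_currency,
)

PAIR = CoefPair(beta_AC=0.001, beta_lnY=-0.157)


class TestFraction:
    def test_zero_alcohol_coefficient_gives_zero(self):
        assert civ_fraction(CoefPair(0.0, -0.2)) == 0.0

    def test_hand_value_at_reported_coefficients(self):
        # exp(-0.001 / -0.157) - 1; differs from a printed 0.671% because
        # published coefficients are rounded to 3 d.p.
        assert civ_fraction(PAIR) == pytest.approx(np.expm1(0.001 / 0.157), rel=1e-14)
        assert civ_fraction(PAIR) == pytest.approx(0.0063897, abs=1e-7)

    def test_zero_income_coefficient_undefined(self):
        with pytest.raises(ZeroDivisionError):
            civ_fraction(CoefPair(0.001, 0.0))

    def test_positive_income_coefficient_warns(self):
        with pytest.warns(UserWarning, match="inverted"):
            civ_fraction(CoefPair(0.001, 0.1))

    @settings(derandomize=True, max_examples=50)
    @given(
        b1=st.floats(min_value=1e-4, max_value=0.05),
        b2=st.floats(min_value=1e-4, max_value=0.05),
        blny=st.floats(min_value=-0.5, max_value=-0.01),
    )
    def test_strictly_increasing_in_beta_ac_when_income_helps(self, b1, b2, blny):
        lo, hi = sorted((b1, b2))
        if lo == hi:
            return
        assert civ_fraction(CoefPair(hi, blny)) > civ_fraction(CoefPair(lo, blny))


class TestGradient:
    def test_hand_values(self):
        g = civ_gradient(PAIR)
        e = np.exp(0.001 / 0.157)
        assert g[0] == pytest.approx(e / 0.157, rel=1e-14)
        assert g[1] == pytest.approx(e * 0.001 / 0.157**2, rel=1e-14)
        assert g[0] == pytest.approx(6.41012, abs=1e-5)
        assert g[1] == pytest.approx(0.040829, abs=1e-6)

    def test_zero_alcohol_coefficient_special_case(self):
        g = civ_gradient(CoefPair(0.0, -0.25))
        assert g[1] == 0.0
        assert g[0] == pytest.approx(1.0 / 0.25)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(3)
        h = 1e-7
        for _ in range(10):
            ba = rng.uniform(-0.01, 0.01)
            by = -rng.uniform(0.05, 0.5)
            g = civ_gradient(CoefPair(ba, by))
            fd_a = (
                civ_fraction(CoefPair(ba + h, by)) - civ_fraction(CoefPair(ba - h, by))
            ) / (2 * h)
            fd_y = (
                civ_fraction(CoefPair(ba, by + h)) - civ_fraction(CoefPair(ba, by - h))
            ) / (2 * h)
            assert g[0] == pytest.approx(fd_a, abs=1e-6)
            assert g[1] == pytest.approx(fd_y, abs=1e-6)


class TestDeltaMethodSE:
    def test_zero_covariance_gives_zero_se(self):
        assert civ_se(CoefPair(0.001, -0.157, np.zeros((2, 2)))) == 0.0

    def test_diagonal_covariance_quadratic_form(self):
        s_a, s_b = 3e-4, 2e-2
        pair = CoefPair(0.001, -0.157, np.diag([s_a**2, s_b**2]))
        g = civ_gradient(pair)
        expected = np.hypot(g[0] * s_a, g[1] * s_b)
        assert civ_se(pair) == pytest.approx(expected, rel=1e-12)
        # and at the frozen gradient values
        assert civ_se(pair) == pytest.approx(
            np.hypot(6.41012 * s_a, 0.040829 * s_b), rel=1e-5
        )

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            CoefPair(0.001, -0.157, np.array([[1e-6, 1e-3], [1e-3, 1e-6]]))

    def test_small_coefficient_limit_linearizes(self):
        # |beta_AC/beta_lnY| < 0.01: tau ~ -beta_AC/beta_lnY within 1%
        for ba, by in [(0.001, -0.157), (0.0005, -0.3), (-0.002, -0.25)]:
            assert abs(ba / by) < 0.01
            tau = civ_fraction(CoefPair(ba, by))
            assert tau == pytest.approx(-ba / by, rel=0.01)


class TestMonetization:
    TOY = IncomeTaxTable(
        age_bands=("a", "b"),
        proportions=(0.5, 0.5),
        incomes=(30_000.0, 40_000.0),
        taxes=(5_000.0, 8_000.0),
    )

    def test_toy_two_band_table(self):
        assert monetize_civ(0.01, self.TOY) == pytest.approx(285.00, abs=1e-9)
        assert round_currency(monetize_civ(0.01, self.TOY)) == 285.00

    def test_zero_tau_zero_pounds(self):
        assert monetize_civ(0.0, self.TOY) == 0.0

    def test_single_band_reduces_to_income_share(self):
        table = IncomeTaxTable(("only",), (1.0,), (30_528.11,), (0.0,))
        tau = civ_fraction(PAIR)
        assert monetize_civ(tau, table) == pytest.approx(tau * 30_528.11, rel=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            IncomeTaxTable(("a", "b"), (0.5, 0.4), (1.0, 1.0), (0.0, 0.0))

    def test_tax_cannot_exceed_income(self):
        with pytest.raises(ValueError, match="income"):
            IncomeTaxTable(("a",), (1.0,), (10_000.0,), (11_000.0,))

    def test_linear_in_tau_and_net_income(self):
        assert monetize_civ(0.02, self.TOY) == pytest.approx(2 * monetize_civ(0.01, self.TOY))
        doubled = IncomeTaxTable(("a", "b"), (0.5, 0.5), (60_000.0, 80_000.0), (10_000.0, 16_000.0))
        assert monetize_civ(0.01, doubled) == pytest.approx(2 * monetize_civ(0.01, self.TOY))


class TestPooling:
    def test_four_component_mean_and_t_interval(self):
        pooled = pool_civ([204.89, 231.26, 178.04, 222.03])
        assert pooled.mean == pytest.approx(209.055, abs=5e-4)
        assert pooled.ci95[0] == pytest.approx(171.84, abs=5e-3)
        assert pooled.ci95[1] == pytest.approx(246.27, abs=5e-3)

    def test_identical_values_zero_width(self):
        pooled = pool_civ([5.0, 5.0, 5.0])
        assert pooled.mean == 5.0
        assert pooled.ci95 == (5.0, 5.0)

    def test_permutation_invariance(self):
        a = pool_civ([1.0, 2.0, 3.0, 4.0])
        b = pool_civ([4.0, 2.0, 1.0, 3.0])
        assert a.mean == b.mean
        assert a.ci95 == b.ci95

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pool_civ([209.0])

    def test_interval_symmetric_about_mean(self):
        p = pool_civ([10.0, 30.0, 12.0, 28.0])
        assert p.mean - p.ci95[0] == pytest.approx(p.ci95[1] - p.mean, rel=1e-12)


class TestConsumptionEquivalents:
    def test_weekly_beer_pint(self):
        # pooled price x 20.45 g/pint / 7 days
        assert convert_consumption_equivalents(209.055, 20.45, 1) == pytest.approx(
            610.74, abs=5e-3
        )

    def test_zero_servings(self):
        assert convert_consumption_equivalents(209.055, 20.45, 0) == 0.0

    def test_linear_in_servings(self):
        one = convert_consumption_equivalents(209.055, 12.5, 1)
        six = convert_consumption_equivalents(209.055, 12.5, 6)
        assert six == pytest.approx(6 * one, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            convert_consumption_equivalents(209.0, 0.0, 1)
        with pytest.raises(ValueError):
            convert_consumption_equivalents(209.0, 20.45, -1)


def test_civ_result_interval_contains_tau_and_scales_to_pounds():
    pair = CoefPair(0.001, -0.157, np.diag([1.3e-4**2, 1.64e-2**2]))
    res = civ_result(pair, TestMonetization.TOY, source="toy")
    assert res.ci95[0] <= res.tau <= res.ci95[1]
    assert res.civ_pounds == pytest.approx(res.tau * 28_500.0, rel=1e-12)
    assert res.se_pounds == pytest.approx(res.se_tau * 28_500.0, rel=1e-12)
    assert res.z == pytest.approx(res.tau / res.se_tau)


def test_tau_interval_coverage_across_simulated_panels():
    """Normal-theory tau CIs cover the generative tau at close to the
    nominal rate across simulated two-wave panels."""
    from affectprice.panel import DesignSpec, fit_wb_random
    from affectprice.pricing import civ_result as _civ
    from affectprice.synthetic import simulate_panel

    spec = DesignSpec(outcome="theta", level1=("alcohol_gday", "ln_income"))
    # cohort-generator default truths; 3000 clusters puts the income
    # coefficient's sampling noise inside the delta method's linear regime
    bw = {"alcohol_gday": 0.02, "ln_income": -0.15}
    tau_true = np.exp(-0.02 / -0.15) - 1.0
    rng = np.random.default_rng(99)
    covered = 0
    B = 1000
    for _ in range(B):
        df = simulate_panel(3000, 2, beta_within=bw, beta_between=bw, mundlak_rho=0.0, seed=rng)
        fit = fit_wb_random(df, spec)
        b, V = fit.coef_pair("alcohol_gday", "ln_income", component="between")
        res = civ_result(CoefPair(b[0], b[1], V), TestMonetization.TOY)
        covered += res.ci95[0] <= tau_true <= res.ci95[1]
    assert 0.93 <= covered / B <= 0.97
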