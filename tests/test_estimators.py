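"""MR estimators: frozen oracles, degenerate cases, equivariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrpath import cochran_q, ivw, mr_egger, wald_ratio, weighted_median
from mrpath.estimators import _weighted_median_point
from mrpath.exceptions import EstimationError


def h_tuple(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return bx, sx, np.asarray(by, float), np.asarray(sy, float)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        ratio, se = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert ratio == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_zero_numerator(self):
        ratio, _ = wald_ratio(0.2, 0.02, 0.0, 0.01)
        assert ratio == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)

    def test_second_order_se_strictly_larger(self):
        _, first = wald_ratio(0.1, 0.03, 0.05, 0.01)
        _, second = wald_ratio(0.1, 0.03, 0.05, 0.01, second_order=True)
        assert second > first

    def test_second_order_se_matches_monte_carlo(self):
        """Oracle: 10^6-draw MC propagation of the ratio distribution."""
        rng = np.random.default_rng(1)
        bx = rng.normal(0.1, 0.01, 10**6)
        by = rng.normal(0.05, 0.01, 10**6)
        mc_sd = (by / bx).std()
        _, second = wald_ratio(0.1, 0.01, 0.05, 0.01, second_order=True)
        assert second == pytest.approx(mc_sd, rel=0.03)


class TestIVW:
    def test_single_snp_degrades_to_wald_ratio(self):
        est, _ = ivw(h_tuple([0.1], [0.05], [0.01]))
        assert est.method == "Wald ratio"
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_perfect_homogeneity(self):
        bx = np.array([0.1, 0.2, 0.3])
        est, het = ivw(h_tuple(bx, 0.4 * bx, [0.01, 0.02, 0.015]))
        assert est.beta == pytest.approx(0.4)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.selected_model == "fixed"

    def test_three_snp_frozen_values(self):
        """Oracle: explicit normal-equations solve of the weighted regression."""
        est, _ = ivw(
            h_tuple([0.1, 0.2, 0.15], [0.02, 0.05, 0.02], [0.01, 0.02, 0.015]),
            model="fixed",
        )
        assert est.beta == pytest.approx(0.19444444, abs=1e-6)
        assert est.se == pytest.approx(0.05773503, abs=1e-6)

    def test_closed_form_matches_wls_regression(self):
        """Dual route: Sigma formulas vs statsmodels zero-intercept WLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        for _ in range(20):
            k = rng.integers(3, 30)
            bx = rng.normal(0.1, 0.05, k)
            by = rng.normal(0.01, 0.02, k)
            sy = rng.uniform(0.005, 0.05, k)
            est, _ = ivw(h_tuple(bx, by, sy), model="fixed")
            fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_effects_se_never_below_fixed(self):
        bx = np.array([0.1, 0.2, 0.15, 0.12])
        by = np.array([0.02, 0.15, 0.01, 0.07])  # heterogeneous
        sy = np.array([0.01, 0.02, 0.015, 0.01])
        fixed, _ = ivw(h_tuple(bx, by, sy), model="fixed")
        random, het = ivw(h_tuple(bx, by, sy), model="random")
        assert random.se >= fixed.se
        assert random.se == pytest.approx(fixed.se * math.sqrt(max(1, het.q / het.df)))

    def test_auto_model_follows_q(self, clean_harmonized):
        est, het = ivw(clean_harmonized, model="auto")
        assert est.extras["model"] == het.selected_model


class TestEgger:
    def test_collinear_null(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        est = mr_egger(h_tuple(bx, 0.3 * bx, [0.01] * 4))
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_two_snps_rejected(self):
        with pytest.raises(EstimationError, match="3"):
            mr_egger(h_tuple([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_matches_wls_regression(self):
        """Independent oracle: statsmodels WLS with intercept, bx oriented >= 0."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        bx = np.abs(rng.normal(0.1, 0.05, 20))
        by = 0.2 * bx + rng.normal(0.01, 0.02, 20)
        sy = rng.uniform(0.01, 0.05, 20)
        est = mr_egger(h_tuple(bx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_orientation_invariance(self):
        """Flipping the sign of (bx, by) pairs leaves Egger unchanged."""
        rng = np.random.default_rng(3)
        bx = rng.normal(0.1, 0.05, 15)
        by = 0.2 * bx + rng.normal(0, 0.01, 15)
        sy = rng.uniform(0.01, 0.05, 15)
        flip = rng.random(15) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        a = mr_egger(h_tuple(bx, by, sy))
        b = mr_egger(h_tuple(bx * sgn, by * sgn, sy))
        assert a.beta == pytest.approx(b.beta)
        assert a.extras["intercept"] == pytest.approx(b.extras["intercept"])


class TestWeightedMedian:
    def test_equal_weights_simple_median(self):
        assert _weighted_median_point(
            np.array([0.1, 0.2, 0.9]), np.array([1.0, 1.0, 1.0])
        ) == pytest.approx(0.2)

    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = weighted_median(h_tuple(bx, 0.7 * bx, [0.01, 0.03, 0.02]), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.7)

    def test_hand_evaluated_interpolation(self):
        """Oracle: hand evaluation of the midpoint cumulative-weight rule.

        ratios 0.1 (w 0.6), 0.5 (0.3), 0.9 (0.1): midpoint cumulative weights
        0.30, 0.75, 0.95; interpolating to 0.5 gives
        0.1 + 0.4*(0.5-0.3)/(0.75-0.3) = 0.2777...
        """
        point = _weighted_median_point(
            np.array([0.1, 0.5, 0.9]), np.array([0.6, 0.3, 0.1])
        )
        assert point == pytest.approx(0.1 + 0.4 * (0.2 / 0.45), abs=1e-12)

    def test_deterministic_given_seed(self, clean_harmonized):
        a = weighted_median(clean_harmonized, n_boot=100, seed=42)
        b = weighted_median(clean_harmonized, n_boot=100, seed=42)
        c = weighted_median(clean_harmonized, n_boot=100, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_too_few_snps_rejected(self):
        with pytest.raises(EstimationError):
            weighted_median(h_tuple([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestCochranQ:
    def test_identical_ratios_no_heterogeneity(self):
        bx = np.array([0.1, 0.2])
        het = cochran_q(h_tuple(bx, 0.5 * bx, [0.01, 0.02]))
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.p == pytest.approx(1.0)
        assert het.selected_model == "fixed"

    def test_single_snp_na(self):
        het = cochran_q(h_tuple([0.1], [0.05], [0.01]))
        assert het.is_na
        assert "fewer than 2" in het.note

    def test_contaminated_set_selects_random_model(self):
        """Oracle: direct Q arithmetic — one ratio 10x the others blows up Q."""
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.05, 0.05, 0.05, 0.5])
        het = cochran_q(h_tuple(bx, by, [0.01] * 4))
        assert het.p < 0.05
        assert het.selected_model == "random"


class TestEstimatorProperties:
    @given(seed=st.integers(0, 50), c=st.sampled_from([0.5, 2.0, -1.5]))
    def test_scale_equivariance(self, seed, c):
        """Scaling (by, sy) by |c| and by by sign(c): beta scales by c."""
        rng = np.random.default_rng(seed)
        k = 8
        bx = rng.normal(0.1, 0.05, k)
        by = rng.normal(0.02, 0.02, k)
        sy = rng.uniform(0.01, 0.05, k)
        base, _ = ivw(h_tuple(bx, by, sy), model="fixed")
        scaled, _ = ivw(h_tuple(bx, c * by, abs(c) * sy), model="fixed")
        assert scaled.beta == pytest.approx(c * base.beta, rel=1e-9)
        egger_base = mr_egger(h_tuple(bx, by, sy))
        egger_scaled = mr_egger(h_tuple(bx, c * by, abs(c) * sy))
        assert egger_scaled.beta == pytest.approx(c * egger_base.beta, rel=1e-9)
        wm_base = weighted_median(h_tuple(bx, by, sy), n_boot=50, seed=1)
        wm_scaled = weighted_median(h_tuple(bx, c * by, abs(c) * sy), n_boot=50, seed=1)
        assert wm_scaled.beta == pytest.approx(c * wm_base.beta, rel=1e-9)

    @given(seed=st.integers(0, 50))
    def test_sign_antisymmetry(self, seed):
        """Negating all outcome effects negates every estimate and the intercept."""
        rng = np.random.default_rng(seed)
        k = 10
        bx = rng.normal(0.1, 0.05, k)
        by = rng.normal(0.02, 0.02, k)
        sy = rng.uniform(0.01, 0.05, k)
        pos, _ = ivw(h_tuple(bx, by, sy), model="fixed")
        neg, _ = ivw(h_tuple(bx, -by, sy), model="fixed")
        assert neg.beta == pytest.approx(-pos.beta, rel=1e-9)
        ep = mr_egger(h_tuple(bx, by, sy))
        en = mr_egger(h_tuple(bx, -by, sy))
        assert en.beta == pytest.approx(-ep.beta, rel=1e-9)
        assert en.extras["intercept"] == pytest.approx(-ep.extras["intercept"], rel=1e-9)
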