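import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from causalmr import (
    UnivariateMR,
    cochran_q,
    egger,
    ivw,
    steiger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from causalmr.univariate import (
    InsufficientInstrumentsError,
    MREstimate,
    UndefinedRatioError,
    _weighted_median_point,
)

from conftest import make_harmonized


class TestWaldRatio:
    def test_hand_division(self):
        ratio, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert ratio == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02)[0] == 0.0

    def test_unit_exposure_is_identity(self):
        ratio, se = wald_ratio(1.0, 0.01, 0.3, 0.05)
        assert (ratio, se) == (0.3, 0.05)

    def test_negative_gamma_se_positive(self):
        ratio, se = wald_ratio(-0.1, 0.01, 0.05, 0.02)
        assert ratio == pytest.approx(-0.5)
        assert se == pytest.approx(0.2)

    def test_zero_gamma_is_error(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIvw:
    def test_hand_weighted_average_and_q(self):
        # ratios {0.5, 1.0} with ratio SEs 0.2: beta 0.75, Q 3.125, RE SE 0.25
        h = make_harmonized([1, 1], [0.01, 0.01], [0.5, 1.0], [0.2, 0.2])
        e = ivw(h)
        assert e.beta == pytest.approx(0.75, abs=1e-12)
        assert e.extras["Q"] == pytest.approx(3.125, abs=1e-12)
        assert e.se == pytest.approx(0.25, abs=1e-12)

    def test_homogeneous_ratios_keep_fixed_se(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.01] * 3)
        e = ivw(h)
        assert e.beta == pytest.approx(0.5)
        assert e.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert e.se == pytest.approx(e.extras["se_fixed"])

    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        e = ivw(h)
        ratio, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert e.beta == pytest.approx(ratio)
        assert e.se == pytest.approx(se)
        assert e.n_snps == 1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    def test_equals_zero_intercept_weighted_regression(self, J, seed):
        rng = np.random.default_rng(seed)
        gamma = rng.uniform(0.03, 0.3, J) * rng.choice([-1, 1], J)
        h = make_harmonized(
            gamma, rng.uniform(0.005, 0.02, J),
            rng.normal(0, 0.05, J), rng.uniform(0.005, 0.05, J),
        )
        w = 1.0 / h.se_Gamma**2
        slope = np.sum(w * h.gamma * h.Gamma) / np.sum(w * h.gamma**2)
        assert ivw(h).beta == pytest.approx(slope, abs=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(3, 20), st.integers(0, 2**31 - 1))
    def test_sign_equivariance(self, J, seed):
        rng = np.random.default_rng(seed)
        h = make_harmonized(
            rng.uniform(0.03, 0.3, J) * rng.choice([-1, 1], J),
            rng.uniform(0.005, 0.02, J),
            rng.normal(0, 0.05, J),
            rng.uniform(0.005, 0.05, J),
        )
        h_both = make_harmonized(-h.gamma, h.se_gamma, -h.Gamma, h.se_Gamma)
        h_out = make_harmonized(h.gamma, h.se_gamma, -h.Gamma, h.se_Gamma)
        for fit in (
            ivw,
            egger,
            lambda x: weighted_median(x, n_boot=2, seed=0),
            lambda x: weighted_mode(x, n_boot=2, seed=0),
        ):
            base = fit(h).beta
            assert fit(h_both).beta == pytest.approx(base, abs=1e-9)
            assert fit(h_out).beta == pytest.approx(-base, abs=1e-9)


class TestCochranQ:
    def test_equal_ratios_give_zero(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.10], [0.01] * 2)
        Q, p = cochran_q(h, 0.5)
        assert Q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_hand_value(self):
        h = make_harmonized([1, 1], [0.01] * 2, [0.5, 1.0], [0.2, 0.2])
        Q, _ = cochran_q(h, 0.75)
        assert Q == pytest.approx(3.125, abs=1e-12)

    def test_planted_outlier_detected(self):
        rng = np.random.default_rng(0)
        J = 30
        gamma = rng.uniform(0.05, 0.2, J)
        Gamma = 0.1 * gamma + rng.normal(0, 0.005, J)
        Gamma[3] += 0.1  # 20 outcome SEs
        h = make_harmonized(gamma, [0.003] * J, Gamma, [0.005] * J)
        _, p = cochran_q(h, ivw(h).beta)
        assert p < 0.05


class TestEgger:
    def test_exact_linear_data_recovered(self):
        gamma = np.array([0.05, 0.10, 0.15, 0.20, 0.30])
        h = make_harmonized(gamma, [0.01] * 5, 0.02 + 0.5 * gamma, [0.02] * 5)
        e = egger(h)
        assert e.beta == pytest.approx(0.5, abs=1e-12)
        assert e.extras["egger_intercept"] == pytest.approx(0.02, abs=1e-12)

    def test_orientation_invariance(self):
        # flipping an instrument's allele coding must not change the fit
        gamma = np.array([0.05, -0.10, 0.15, 0.20])
        Gamma = 0.01 + 0.4 * gamma
        h1 = make_harmonized(gamma, [0.01] * 4, Gamma, [0.02] * 4)
        flip = np.array([1, -1, 1, 1.0])
        h2 = make_harmonized(gamma * flip, [0.01] * 4, Gamma * flip, [0.02] * 4)
        assert egger(h1).beta == pytest.approx(egger(h2).beta, abs=1e-12)

    def test_agrees_with_statsmodels_wls(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        J = 40
        gamma = rng.uniform(0.03, 0.3, J)
        se_G = rng.uniform(0.01, 0.05, J)
        Gamma = 0.01 + 0.3 * gamma + rng.normal(0, 3 * se_G)  # overdispersed
        h = make_harmonized(gamma, [0.01] * J, Gamma, se_G)
        e = egger(h)
        X = statsmodels.add_constant(gamma)
        fit = statsmodels.WLS(Gamma, X, weights=1.0 / se_G**2).fit()
        assert e.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert e.extras["egger_intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        # overdispersed data: multiplicative scale > 1, so SEs match WLS's
        assert e.se == pytest.approx(fit.bse[1], rel=1e-8)

    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_harmonized([1, 1, 1], [0.01] * 3, [0.0, 1.0, 2.0], [0.1] * 3)
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(1.0)

    def test_hand_interpolation(self):
        # ratios {1,2,10}, weights {0.3,0.3,0.4} → cumulative midpoints
        # 0.15/0.45/0.80 → interpolate at 0.5 → 3.1429
        beta = _weighted_median_point(
            np.array([1.0, 2.0, 10.0]), np.array([0.3, 0.3, 0.4])
        )
        assert beta == pytest.approx(3.142857142857143, abs=1e-9)

    def test_equal_weights_odd_j_is_sample_median(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0, 1, 9)
        assert _weighted_median_point(b, np.ones(9)) == pytest.approx(
            float(np.median(b)), abs=1e-12
        )

    def test_bootstrap_se_reproducible(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.02] * 3)
        e1 = weighted_median(h, n_boot=100, seed=42)
        e2 = weighted_median(h, n_boot=100, seed=42)
        assert e1.se == e2.se > 0


class TestWeightedMode:
    def test_identical_ratios(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.02] * 3)
        assert weighted_mode(h, n_boot=10, seed=0).beta == pytest.approx(0.5, abs=1e-9)

    def test_cluster_dominates_outlier(self):
        gamma = np.ones(4)
        h = make_harmonized(gamma, [0.01] * 4, [0.99, 1.00, 1.01, 5.0], [0.1] * 4)
        e = weighted_mode(h, phi=0.5, n_boot=10, seed=0)
        assert e.beta == pytest.approx(1.0, abs=0.05)


class TestSteiger:
    def test_strong_exposure_weak_outcome(self):
        J = 20
        h = make_harmonized([0.09] * J, [0.01] * J, [0.01] * J, [0.01] * J)
        res = steiger(h, n_exposure=1e5, n_outcome=1e5)
        assert res.direction == "exposure_to_outcome"
        assert res.pval < 1e-3

    def test_symmetric_statistics(self):
        h = make_harmonized([0.05] * 5, [0.01] * 5, [0.05] * 5, [0.01] * 5)
        res = steiger(h, 1e5, 1e5)
        assert res.r2_exposure == pytest.approx(res.r2_outcome)

    def test_single_snp_formula(self):
        # t=10, n=1e5 → R² = 100/(100 + 99998) ≈ 0.001
        h = make_harmonized([0.1], [0.01], [0.001], [0.01])
        res = steiger(h, 1e5, 1e5)
        assert res.r2_exposure == pytest.approx(100 / (100 + 1e5 - 2), rel=1e-12)

    def test_missing_sample_size_is_error(self):
        h = make_harmonized([0.1], [0.01], [0.001], [0.01])
        with pytest.raises(ValueError):
            steiger(h)


class TestOddsRatioConversion:
    @pytest.mark.parametrize(
        "beta,expected_or",
        [(math.log(0.91), 0.91), (0.0, 1.0), (0.7608, 2.14)],
    )
    def test_exponentiation(self, beta, expected_or):
        e = MREstimate("IVW", beta, 0.05, 10)
        or_, lo, hi = to_odds_ratio(e)
        assert or_ == pytest.approx(expected_or, abs=5e-3)
        assert lo < or_ < hi


class TestUnivariateModel:
    def test_fit_all_returns_suite(self):
        rng = np.random.default_rng(3)
        J = 20
        gamma = rng.uniform(0.05, 0.2, J)
        h = make_harmonized(gamma, [0.01] * J, 0.2 * gamma + rng.normal(0, 0.01, J), [0.01] * J)
        model = UnivariateMR(h)
        estimates = model.fit_all(n_boot=20, seed=0)
        assert [e.method for e in estimates] == [
            "Inverse variance weighted", "MR Egger", "Weighted median", "Weighted mode",
        ]
        Q, p = model.heterogeneity()
        assert Q >= 0 and 0 < p <= 1

    def test_per_snp_table_carries_ratios(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02, 0.01])
        df = UnivariateMR(h).per_snp_table()
        np.testing.assert_allclose(df["ratio"], [0.5, 0.5])
        np.testing.assert_allclose(df["ratio_se"], [0.2, 0.05])
        np.testing.assert_allclose(df["precision"], 1 / df["ratio_se"])

    def test_unknown_method_rejected(self):
        model = UnivariateMR.from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(ValueError, match="unknown method"):
            model.fit("banana")
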