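import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    egger_normal_equations,
    make_pair,
    random_pairs,
    ratio_pairs,
    weighted_median_by_hand,
)
from periomr.estimators import (
    InsufficientInstrumentsError,
    SingularDesignError,
    UndefinedRatioError,
    cochran_q,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(make_pair("rs1", bx=0.04, by=0.008, sey=0.002))
        assert est.ratio == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        assert wald_ratio(make_pair(by=0.0)).ratio == 0.0

    def test_negative_exposure_effect_handled_via_absolute_se(self):
        est = wald_ratio(make_pair(bx=-0.04, by=0.008, sey=0.002))
        assert est.ratio == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.05)

    def test_zero_exposure_effect_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(make_pair(bx=0.0))


class TestIVW:
    def test_hand_computed_weighted_mean(self):
        pairs = ratio_pairs([0.2, 0.1], [0.05, 0.1])
        est = ivw(pairs, mode="fixed")
        # weights 400 and 100: (400*0.2 + 100*0.1) / 500
        assert est.theta == pytest.approx(0.18)
        assert est.se == pytest.approx(500**-0.5)

    def test_single_instrument_reduces_to_wald_ratio(self):
        pair = make_pair("rs1", bx=0.05, by=0.012, sey=0.004)
        wald = wald_ratio(pair)
        est = ivw([pair], mode="fixed")
        assert est.theta == pytest.approx(wald.ratio)
        assert est.se == pytest.approx(wald.se)
        est_rand = ivw([pair], mode="random")
        assert est_rand.se == pytest.approx(wald.se)

    def test_identical_ratios_give_zero_heterogeneity(self):
        pairs = ratio_pairs([0.25, 0.25, 0.25], [0.1, 0.2, 0.05])
        est = ivw(pairs)
        assert est.theta == pytest.approx(0.25)
        assert est.q_stat == pytest.approx(0.0)
        assert est.q_p == pytest.approx(1.0)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pairs = random_pairs(rng, 8)
            assert ivw(pairs, "random").se >= ivw(pairs, "fixed").se - 1e-15

    def test_equals_weighted_regression_through_origin(self):
        """Ratio pooling is algebraically a weighted origin regression."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            pairs = random_pairs(rng, 12)
            bx = np.array([p.beta_exposure for p in pairs])
            by = np.array([p.beta_outcome for p in pairs])
            w = np.array([p.se_outcome for p in pairs]) ** -2.0
            slope = sm.WLS(by, bx, weights=w).fit().params[0]
            assert ivw(pairs, "fixed").theta == pytest.approx(slope, rel=1e-10)

    def test_no_instruments_is_an_error(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([])


class TestEgger:
    def test_exact_proportional_data(self):
        pairs = [make_pair(f"rs{i}", bx, 0.3 * bx, 0.01) for i, bx in enumerate([0.02, 0.05, 0.1, 0.2])]
        est = egger(pairs)
        assert est.theta == pytest.approx(0.3)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_data_recovers_slope_and_intercept(self):
        pairs = [
            make_pair(f"rs{i}", bx, 0.01 + 0.3 * bx, 0.01)
            for i, bx in enumerate([0.02, 0.05, 0.1, 0.2, 0.3])
        ]
        est = egger(pairs)
        assert est.theta == pytest.approx(0.3)
        assert est.intercept == pytest.approx(0.01)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            pairs = random_pairs(rng, 5)
            est = egger(pairs)
            b0, b1, se0, se1 = egger_normal_equations(pairs)
            assert est.intercept == pytest.approx(b0, rel=1e-9)
            assert est.theta == pytest.approx(b1, rel=1e-9)
            assert est.intercept_se == pytest.approx(se0, rel=1e-9)
            assert est.se == pytest.approx(se1, rel=1e-9)

    def test_intercept_constrained_to_zero_is_ivw(self):
        """Origin-constrained Egger under the same weights is the IVW estimate."""
        rng = np.random.default_rng(3)
        pairs = random_pairs(rng, 10)
        bx = np.abs(np.array([p.beta_exposure for p in pairs]))
        by = np.array([p.beta_outcome for p in pairs]) * np.sign(
            [p.beta_exposure for p in pairs]
        )
        w = np.array([p.se_outcome for p in pairs]) ** -2.0
        constrained_slope = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        assert ivw(pairs, "fixed").theta == pytest.approx(constrained_slope, rel=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(ratio_pairs([0.1, 0.2], [0.1, 0.1]))

    def test_zero_exposure_spread_is_singular(self):
        pairs = [make_pair(f"rs{i}", 0.1, y, 0.01) for i, y in enumerate([0.01, 0.02, 0.03])]
        with pytest.raises(SingularDesignError):
            egger(pairs)


class TestWeightedMedian:
    def test_equal_weights_hit_middle_ratio(self):
        pairs = ratio_pairs([0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        est = weighted_median(pairs, n_boot=50, seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_unequal_weights_interpolate(self):
        # weights 1, 1, 2 realised through se(r) = 1, 1, 1/sqrt(2)
        pairs = ratio_pairs([0.0, 0.2, 0.4], [1.0, 1.0, 2**-0.5])
        est = weighted_median(pairs, n_boot=50, seed=1)
        assert est.theta == pytest.approx(0.2 + 0.2 * (0.5 - 0.375) / (0.75 - 0.375))
        assert est.theta == pytest.approx(0.2667, abs=5e-5)

    def test_constant_ratios_recover_constant(self):
        pairs = ratio_pairs([0.7, 0.7, 0.7, 0.7], [0.3, 0.1, 0.2, 0.05])
        assert weighted_median(pairs, n_boot=50, seed=9).theta == pytest.approx(0.7)

    def test_matches_hand_interpolation_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            pairs = random_pairs(rng, 7)
            ratios = [p.beta_outcome / p.beta_exposure for p in pairs]
            weights = [(abs(p.beta_exposure) / p.se_outcome) ** 2 for p in pairs]
            est = weighted_median(pairs, n_boot=20, seed=2)
            assert est.theta == pytest.approx(weighted_median_by_hand(ratios, weights))

    def test_seed_reproducibility_of_bootstrap_se(self):
        pairs = ratio_pairs([0.1, 0.15, 0.3, 0.05], [0.1, 0.2, 0.15, 0.1])
        a = weighted_median(pairs, n_boot=100, seed=42)
        b = weighted_median(pairs, n_boot=100, seed=42)
        c = weighted_median(pairs, n_boot=100, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(ratio_pairs([0.1, 0.2, 0.3], [0.1] * 3), seed=None)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(ratio_pairs([0.1, 0.2], [0.1, 0.1]), seed=0)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        q, df, p = cochran_q(ratio_pairs([0.2, 0.2, 0.2], [0.1, 0.1, 0.1]), 0.2)
        assert q == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        q, df, _ = cochran_q(ratio_pairs([0.1, 0.3], [0.1, 0.1]), 0.2)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_minimised_at_ivw_estimate(self):
        rng = np.random.default_rng(12)
        pairs = random_pairs(rng, 9)
        theta_ivw = ivw(pairs, "fixed").theta
        q_at_ivw = cochran_q(pairs, theta_ivw)[0]
        for theta in np.linspace(theta_ivw - 0.5, theta_ivw + 0.5, 41):
            assert q_at_ivw <= cochran_q(pairs, float(theta))[0] + 1e-12

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(ratio_pairs([0.1], [0.1]), 0.1)


@settings(max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000), j=st.integers(3, 12))
def test_permutation_and_reorientation_invariance(seed, j):
    """Estimates must not depend on instrument order, nor on negating
    both betas of any single instrument."""
    rng = np.random.default_rng(seed)
    pairs = random_pairs(rng, j)
    perm = list(rng.permutation(j))
    permuted = [pairs[i] for i in perm]
    k = int(rng.integers(j))
    p = pairs[k]
    reoriented = list(pairs)
    reoriented[k] = make_pair(p.snp_id, -p.beta_exposure, -p.beta_outcome, p.se_outcome, p.se_exposure)
    for variant in (permuted, reoriented):
        assert ivw(variant).theta == pytest.approx(ivw(pairs).theta, rel=1e-9)
        assert egger(variant).theta == pytest.approx(egger(pairs).theta, rel=1e-9)
        assert weighted_median(variant, n_boot=10, seed=0).theta == pytest.approx(
            weighted_median(pairs, n_boot=10, seed=0).theta, rel=1e-9
        )


@settings(max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0))
def test_outcome_scale_equivariance(seed, c):
    """Scaling outcome betas and SEs by c scales every theta by c."""
    rng = np.random.default_rng(seed)
    pairs = random_pairs(rng, 8)
    scaled = [
        make_pair(p.snp_id, p.beta_exposure, c * p.beta_outcome, c * p.se_outcome, p.se_exposure)
        for p in pairs
    ]
    assert ivw(scaled).theta == pytest.approx(c * ivw(pairs).theta, rel=1e-9)
    assert egger(scaled).theta == pytest.approx(c * egger(pairs).theta, rel=1e-9)
    assert weighted_median(scaled, n_boot=10, seed=1).theta == pytest.approx(
        c * weighted_median(pairs, n_boot=10, seed=1).theta, rel=1e-9
    )


@settings(max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_weighted_median_bounded_by_extreme_ratios(seed):
    rng = np.random.default_rng(seed)
    pairs = random_pairs(rng, 6)
    ratios = [p.beta_outcome / p.beta_exposure for p in pairs]
    theta = weighted_median(pairs, n_boot=5, seed=0).theta
    assert min(ratios) - 1e-12 <= theta <= max(ratios) + 1e-12
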