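import math

import numpy as np
import pytest

from bimr import (
    HarmonizedSet,
    ivw,
    mode_estimate,
    mr_egger,
    run_all_methods,
    wald_ratio,
    weighted_median,
)
from bimr.estimators import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    wald_arrays,
)

from conftest import hset_from_ratios, random_hset


class TestWaldRatio:
    def test_basic_arithmetic(self):
        theta, se = wald_ratio(0.1, 0.05, 0.01)
        assert theta == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        theta, _ = wald_ratio(0.1, 0.0, 0.01)
        assert theta == 0.0

    def test_negative_exposure_effect_uses_absolute_value_for_se(self):
        theta, se = wald_ratio(-0.2, 0.05, 0.02)
        assert theta == pytest.approx(-0.25)
        assert se == pytest.approx(0.1)

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.05, 0.01)


class TestIVW:
    def test_identical_ratios_reduce_to_wald(self):
        h = hset_from_ratios([0.5, 0.5], [1.0, 1.0])
        assert ivw(h).beta == pytest.approx(0.5, abs=1e-14)

    def test_equal_weights_give_plain_mean(self):
        h = hset_from_ratios([0.2, 0.4], [2.0, 2.0])
        assert ivw(h).beta == pytest.approx(0.3, abs=1e-14)

    def test_weighted_mean_and_fixed_se_closed_form(self):
        h = hset_from_ratios([0.1, 0.3, 0.5], [4.0, 1.0, 1.0])
        est = ivw(h, effects_model="fixed")
        assert est.beta == pytest.approx(0.2, abs=1e-14)
        assert est.se == pytest.approx(6 ** -0.5, abs=1e-14)

    def test_multiplicative_random_floors_at_fixed(self):
        # homogeneous ratios: Q ~ 0, the scale factor floors at 1
        h = hset_from_ratios([0.3, 0.3, 0.3], [1.0, 2.0, 3.0])
        fixed = ivw(h, "fixed")
        mre = ivw(h, "multiplicative_random")
        assert mre.se == pytest.approx(fixed.se)

    def test_single_pair_is_insufficient(self):
        h = hset_from_ratios([0.5], [1.0])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)

    def test_closed_form_equals_weighted_regression(self, rng):
        """IVW as a weighted mean of ratios vs the zero-intercept WLS slope."""
        import statsmodels.api as sm

        for _ in range(50):
            h = random_hset(rng, j=int(rng.integers(3, 20)), theta=float(rng.normal(0, 0.3)))
            est = ivw(h, "fixed")
            fit = sm.WLS(h.beta_out, h.beta_exp, weights=1.0 / h.se_out**2).fit()
            assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-12)
            # fixed-effect SE corresponds to the unscaled covariance
            unscaled_se = float(np.sqrt(np.asarray(fit.cov_params())[0, 0] / fit.scale))
            assert est.se == pytest.approx(unscaled_se, abs=1e-12)

    def test_or_scale_is_exponentiated(self):
        h = hset_from_ratios([0.1, 0.3, 0.5], [4.0, 1.0, 1.0])
        est = ivw(h)
        assert est.or_ == pytest.approx(math.exp(est.beta))
        assert est.or_low == pytest.approx(math.exp(est.ci_low))
        assert est.ci_low < est.beta < est.ci_high


class TestEgger:
    def test_noiseless_line_recovered_exactly(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3, 0.4])
        by = 0.02 + 0.5 * bx
        h = HarmonizedSet.from_arrays(bx, 0.01 * np.ones(5), by, 0.01 * np.ones(5))
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.02, abs=1e-12)

    def test_proportional_effects_give_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        h = HarmonizedSet.from_arrays(bx, 0.01 * np.ones(4), 0.3 * bx, 0.02 * np.ones(4))
        slope, intercept = mr_egger(h)
        assert intercept.intercept == pytest.approx(0.0, abs=1e-12)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)

    def test_matches_independent_gls_oracle(self, rng):
        """Egger fit vs statsmodels GLS with exact outcome-variance weights."""
        import statsmodels.api as sm

        for _ in range(20):
            j = 10
            bx = rng.uniform(0.05, 0.4, j)
            se_out = rng.uniform(0.005, 0.05, j)
            by = 0.05 + 0.3 * bx + rng.normal(0, se_out)
            h = HarmonizedSet.from_arrays(bx, 0.01 * np.ones(j), by, se_out)
            slope, intercept = mr_egger(h)
            X = sm.add_constant(bx)
            fit = sm.GLS(by, X, sigma=np.diag(se_out**2)).fit()
            assert intercept.intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
            assert slope.beta == pytest.approx(float(fit.params[1]), abs=1e-10)
            # SE convention: multiplicative overdispersion floored at 1
            unscaled = np.asarray(fit.cov_params()) / fit.scale
            want_se = np.sqrt(np.diag(unscaled) * max(1.0, float(fit.mse_resid)))
            assert intercept.se == pytest.approx(float(want_se[0]), abs=1e-10)
            assert slope.se == pytest.approx(float(want_se[1]), abs=1e-10)

    def test_orientation_invariance_to_allele_relabelling(self, rng):
        h = random_hset(rng, j=8, theta=0.25)
        bx, by = h.beta_exp, h.beta_out
        flip = rng.choice([1.0, -1.0], 8)
        h2 = HarmonizedSet.from_arrays(bx * flip, h.se_exp, by * flip, h.se_out)
        s1, i1 = mr_egger(h)
        s2, i2 = mr_egger(h2)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1.intercept == pytest.approx(i2.intercept, abs=1e-12)

    def test_two_pairs_insufficient(self):
        h = hset_from_ratios([0.1, 0.2], [1.0, 1.0])
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weights_give_plain_median(self):
        h = hset_from_ratios([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert weighted_median(h, n_boot=100, seed=1).beta == pytest.approx(2.0)

    def test_majority_weight_dominates(self):
        h = hset_from_ratios([0.1, 0.2, 5.0], [1.0, 1.0, 10.0])
        est = weighted_median(h, n_boot=100, seed=1)
        assert abs(est.beta - 5.0) < 1.5

    def test_gross_outlier_ignored(self):
        h = hset_from_ratios([0.0, 0.1, 0.2, 5.0], [1.0, 1.0, 1.0, 1.0])
        est = weighted_median(h, n_boot=100, seed=1)
        # hand interpolation: s = (.125,.375,.625,.875); 0.5 falls between
        # theta_(2)=0.1 (s=.375) and theta_(3)=0.2 (s=.625) -> 0.15
        assert est.beta == pytest.approx(0.15, abs=1e-12)

    def test_matches_brute_force_interpolation(self, rng):
        for _ in range(20):
            j = int(rng.integers(3, 12))
            theta = rng.normal(0, 1, j)
            w = rng.uniform(0.1, 5.0, j)
            h = hset_from_ratios(theta, w)
            est = weighted_median(h, n_boot=100, seed=2)
            order = np.argsort(theta)
            th, p = theta[order], w[order] / w.sum()
            s = np.cumsum(p) - p / 2
            assert est.beta == pytest.approx(float(np.interp(0.5, s, th)), abs=1e-12)

    def test_bootstrap_se_is_seeded(self):
        h = hset_from_ratios([0.1, 0.2, 0.3, 0.4], [1.0, 2.0, 1.0, 2.0])
        a = weighted_median(h, n_boot=200, seed=9)
        b = weighted_median(h, n_boot=200, seed=9)
        assert a == b


class TestModeEstimators:
    def test_dominant_cluster_wins(self):
        h = hset_from_ratios([0.3, 0.3, 0.3, 9.0], [1.0, 1.0, 1.0, 1.0])
        est = mode_estimate(h, weighted=False, n_boot=100, seed=3)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_all_identical_ratios_degenerate_bandwidth(self):
        h = hset_from_ratios([0.7, 0.7, 0.7], [1.0, 2.0, 3.0])
        est = mode_estimate(h, weighted=False, n_boot=100, seed=3)
        assert est.beta == pytest.approx(0.7)

    def test_weights_move_the_mode_between_clusters(self):
        theta = [0.1] * 6 + [0.8] * 3
        w = [1.0] * 6 + [10.0] * 3
        h = hset_from_ratios(theta, w)
        simple = mode_estimate(h, weighted=False, n_boot=100, seed=4)
        weighted = mode_estimate(h, weighted=True, n_boot=100, seed=4)
        assert abs(simple.beta - 0.1) < 0.05
        assert abs(weighted.beta - 0.8) < 0.05

    def test_matches_brute_force_density_argmax(self, rng):
        """Kernel-density mode vs direct evaluation on the ratio grid."""
        theta = rng.normal(0.2, 0.5, 9)
        w = rng.uniform(0.5, 3.0, 9)
        h = hset_from_ratios(theta, w)
        est = mode_estimate(h, weighted=True, phi=1.0, n_boot=100, seed=5)
        p = w / w.sum()
        mean = float(np.sum(p * theta))
        sd = math.sqrt(float(np.sum(p * (theta - mean) ** 2)) * 9 / 8)
        order = np.argsort(theta)
        s_ = np.cumsum(p[order]) - p[order] / 2
        q75 = float(np.interp(0.75, s_, theta[order]))
        q25 = float(np.interp(0.25, s_, theta[order]))
        bw = 0.9 * min(sd, (q75 - q25) / 1.349) * 9 ** (-0.2)
        dens = [float(np.sum(p * np.exp(-0.5 * ((t - theta) / bw) ** 2)))
                for t in theta]
        assert est.beta == pytest.approx(float(theta[int(np.argmax(dens))]), abs=1e-12)


class TestRunAllMethods:
    def test_noiseless_proportional_set_agrees_across_methods(self):
        theta = math.log(0.92)
        bx = np.array([0.08, 0.1, 0.12, 0.15, 0.2, 0.3])
        h = HarmonizedSet.from_arrays(
            bx, 0.01 * np.ones(6), theta * bx, 0.01 * np.ones(6)
        )
        out = run_all_methods(h, n_boot=100, seed=0)
        for method in ("egger", "weighted_median", "ivw", "simple_mode", "weighted_mode"):
            assert out[method] is not None
            assert out[method].or_ == pytest.approx(0.92, abs=1e-9)

    def test_two_pair_set_gates_everything_but_ivw(self):
        h = hset_from_ratios([0.1, 0.2], [1.0, 1.0])
        out = run_all_methods(h, n_boot=100)
        assert out["ivw"] is not None
        assert out["egger"] is None
        assert out["weighted_median"] is None
        assert out["simple_mode"] is None

    def test_single_pair_falls_back_to_wald_ratio(self):
        h = hset_from_ratios([0.5], [4.0])
        out = run_all_methods(h, n_boot=100)
        assert out["ivw"].method == "wald"
        assert out["ivw"].beta == pytest.approx(0.5, abs=1e-12)

    def test_fixed_seed_output_is_stable(self, rng):
        h = random_hset(rng, j=8, theta=0.1)
        a = run_all_methods(h, n_boot=200, seed=11)
        b = run_all_methods(h, n_boot=200, seed=11)
        assert a == b


def test_all_estimators_invariant_to_joint_negation(rng):
    """Relabelling any SNP's alleles (negating both betas) changes nothing."""
    h = random_hset(rng, j=9, theta=0.15)
    flip = rng.choice([1.0, -1.0], 9)
    h2 = HarmonizedSet.from_arrays(
        h.beta_exp * flip, h.se_exp, h.beta_out * flip, h.se_out
    )
    theta1, se1, w1 = wald_arrays(h)
    theta2, se2, w2 = wald_arrays(h2)
    assert np.allclose(theta1, theta2, atol=1e-15)
    assert np.allclose(w1, w2, atol=1e-15)
    assert ivw(h).beta == pytest.approx(ivw(h2).beta, abs=1e-12)
    assert weighted_median(h, 100, 6).beta == pytest.approx(
        weighted_median(h2, 100, 6).beta, abs=1e-12
    )
    assert mode_estimate(h, True, 1.0, 100, 6).beta == pytest.approx(
        mode_estimate(h2, True, 1.0, 100, 6).beta, abs=1e-12
    )
    assert mr_egger(h)[0].beta == pytest.approx(mr_egger(h2)[0].beta, abs=1e-12)
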