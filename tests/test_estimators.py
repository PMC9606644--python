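"""Estimator correctness: arithmetic cases, oracle equivalences, symmetries."""

import numpy as np
import pytest
import statsmodels.api as sm

from tsmr.estimators import (
    IVW_FIXED,
    IVW_MRE,
    confidence_interval,
    egger,
    ivw,
    mode_estimate,
    mode_point,
    wald_ratio,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)
from tsmr.harmonize import HarmonizedDataset

from conftest import dataset_from_arrays


class TestWaldRatio:
    def test_arithmetic(self):
        d = dataset_from_arrays([0.5], [0.01], [0.1], [0.05])
        w = wald_ratio(d.pairs[0])
        assert w.ratio == pytest.approx(0.2)
        assert w.ratio_se == pytest.approx(0.1)
        assert w.weight == pytest.approx(100.0)

    def test_zero_outcome_effect(self):
        d = dataset_from_arrays([0.5], [0.01], [0.0], [0.05])
        assert wald_ratio(d.pairs[0]).ratio == 0.0

    def test_joint_negation_symmetry(self):
        a = dataset_from_arrays([0.5], [0.01], [0.1], [0.05])
        b = dataset_from_arrays([-0.5], [0.01], [-0.1], [0.05])
        assert wald_ratio(a.pairs[0]).ratio == wald_ratio(b.pairs[0]).ratio
        assert wald_ratio(a.pairs[0]).ratio_se == wald_ratio(b.pairs[0]).ratio_se

    def test_zero_exposure_effect_excluded_with_warning(self, caplog):
        d = dataset_from_arrays([0.5, 0.0], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05])
        with caplog.at_level("WARNING"):
            ratios = wald_ratios(d)
        assert len(ratios) == 1


class TestIVW:
    def test_single_pair_degenerates_to_wald_ratio(self):
        d = dataset_from_arrays([0.5], [0.01], [0.1], [0.05])
        est = ivw(d)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_equal_weights_average(self):
        d = dataset_from_arrays([1.0, 1.0], [0.01, 0.01], [0.1, 0.3], [0.05, 0.05])
        assert ivw(d, model=IVW_FIXED).beta == pytest.approx(0.2)

    def test_matches_wls_through_origin(self, random_dataset):
        est = ivw(random_dataset, model=IVW_FIXED)
        fit = sm.WLS(
            random_dataset.beta_out,
            random_dataset.beta_exp,
            weights=1.0 / random_dataset.se_out**2,
        ).fit()
        assert est.beta == pytest.approx(float(fit.params[0]), rel=1e-10)
        # fixed-effect se is the WLS se with the residual scale divided out
        assert est.se == pytest.approx(
            float(fit.bse[0] / np.sqrt(fit.scale)), rel=1e-10
        )

    def test_random_effects_never_narrower_than_fixed(self, random_dataset):
        assert ivw(random_dataset, model=IVW_MRE).se >= ivw(
            random_dataset, model=IVW_FIXED
        ).se

    def test_ci_brackets_beta(self, random_dataset):
        est = ivw(random_dataset)
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.ci_high - est.beta == pytest.approx(1.959964 * est.se)


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        bx = np.array([0.02, 0.05, 0.08, 0.11, 0.14])
        by = 0.05 + 0.2 * bx
        d = dataset_from_arrays(bx, np.full(5, 0.004), by, np.full(5, 0.01))
        est = egger(d)
        assert est.beta == pytest.approx(0.2, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.05, abs=1e-10)

    def test_orientation_invariance(self, random_dataset):
        flipped_pairs = []
        for i, p in enumerate(random_dataset.pairs):
            if i % 3 == 0:
                import dataclasses

                p = dataclasses.replace(p, beta_exp=-p.beta_exp, beta_out=-p.beta_out)
            flipped_pairs.append(p)
        other = HarmonizedDataset(tuple(flipped_pairs))
        a, b = egger(random_dataset), egger(other)
        assert b.beta == pytest.approx(a.beta, rel=1e-10)
        assert b.se == pytest.approx(a.se, rel=1e-10)

    def test_zero_intercept_model_recovers_fixed_ivw(self, random_dataset):
        """Constraining the Egger intercept to zero is exactly fixed-effect IVW."""
        fit = sm.WLS(
            random_dataset.beta_out,
            random_dataset.beta_exp,
            weights=1.0 / random_dataset.se_out**2,
        ).fit()
        assert float(fit.params[0]) == pytest.approx(
            ivw(random_dataset, model=IVW_FIXED).beta, rel=1e-10
        )

    def test_too_few_instruments(self):
        d = dataset_from_arrays([0.1, 0.2], [0.01, 0.01], [0.02, 0.04], [0.01, 0.01])
        with pytest.raises(ValueError, match="insufficient"):
            egger(d)

    def test_t_based_ci_uses_n_minus_2_df(self, random_dataset):
        from scipy import stats

        est = egger(random_dataset)
        q = stats.t.ppf(0.975, est.n_snp - 2)
        assert est.ci_high - est.beta == pytest.approx(q * est.se)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert weighted_median_point(r, np.ones(5)) == pytest.approx(3.0)

    def test_constant_ratios(self):
        bx = np.full(5, 0.1)
        d = dataset_from_arrays(bx, np.full(5, 0.004), 0.3 * bx, np.full(5, 0.01))
        est = weighted_median(d, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 0.35  # bootstrap noise only

    def test_robust_to_minority_invalid_instruments(self, rng):
        n, shifted = 15, 7
        bx = rng.normal(0.1, 0.01, n)
        sy = np.full(n, 0.002)
        by = 0.2 * bx + rng.normal(0, sy)
        by[:shifted] += 0.05  # invalid minority, ratio shift +0.5
        d = dataset_from_arrays(bx, np.full(n, 0.004), by, sy)
        wm = weighted_median(d, n_boot=200, seed=2)
        mean_ratio = np.mean(by / bx)
        assert abs(wm.beta - 0.2) < 0.1
        assert abs(wm.beta - 0.2) < abs(mean_ratio - 0.2)

    def test_seed_reproducibility(self, random_dataset):
        a = weighted_median(random_dataset, n_boot=100, seed=7)
        b = weighted_median(random_dataset, n_boot=100, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestMode:
    def test_dominant_cluster_ignores_outlier(self):
        r = np.array([0.2, 0.2, 0.2, 5.0])
        assert mode_point(r, np.ones(4)) == pytest.approx(0.2, abs=0.3)

    def test_simple_and_weighted_agree_with_equal_weights(self):
        bx = np.array([0.1, 0.12, 0.09, 0.11, 0.1])
        by = np.array([0.02, 0.05, 0.01, 0.04, 0.03])
        sy = 0.01 * bx / 0.1  # makes all IVW weights equal
        d = dataset_from_arrays(bx, np.full(5, 0.004), by, sy)
        s = mode_estimate(d, weighted=False, n_boot=0)
        w = mode_estimate(d, weighted=True, n_boot=0)
        assert w.beta == pytest.approx(s.beta, abs=1e-9)

    def test_weighted_mode_follows_heavier_cluster(self, rng):
        # two clusters of equal tightness in ratio space: 4 SNPs at ratio
        # ~0.1 carrying large IVW weights, 6 SNPs at ratio ~0.6 with small
        r = np.concatenate([np.full(4, 0.1), np.full(6, 0.6)])
        r += rng.normal(0, 0.001, 10)
        bx = np.concatenate([np.full(4, 0.2), np.full(6, 0.05)])
        by = r * bx
        sy = np.concatenate([np.full(4, 0.002), np.full(6, 0.02)])
        d = dataset_from_arrays(bx, np.full(10, 0.004), by, sy)
        w = mode_estimate(d, weighted=True, n_boot=0)
        s = mode_estimate(d, weighted=False, n_boot=0)
        assert abs(w.beta - 0.1) < 0.15
        assert abs(s.beta - 0.6) < 0.2

    def test_too_few_instruments(self):
        d = dataset_from_arrays([0.1, 0.2], [0.01, 0.01], [0.02, 0.04], [0.01, 0.01])
        with pytest.raises(ValueError):
            mode_estimate(d)

    def test_seed_reproducibility(self, random_dataset):
        a = mode_estimate(random_dataset, weighted=True, n_boot=100, seed=3)
        b = mode_estimate(random_dataset, weighted=True, n_boot=100, seed=3)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestConfidenceInterval:
    def test_standard_normal_quantile(self):
        lo, hi = confidence_interval(0.0, 1.0)
        assert (round(lo, 3), round(hi, 3)) == (-1.960, 1.960)

    def test_t_quantile_wider_than_normal(self):
        n_lo, n_hi = confidence_interval(0.0, 1.0)
        t_lo, t_hi = confidence_interval(0.0, 1.0, dist="t", df=5)
        assert t_hi > n_hi and t_lo < n_lo

    def test_t_requires_df(self):
        with pytest.raises(ValueError):
            confidence_interval(0.0, 1.0, dist="t")


@pytest.mark.parametrize("method", ["ivw", "egger", "wm", "simple", "weighted"])
def test_scale_and_sign_equivariance(random_dataset, method):
    """Multiplying outcome effects by c scales beta and se by |c|; negation
    flips beta and preserves se."""

    def run(data):
        if method == "ivw":
            return ivw(data)
        if method == "egger":
            return egger(data)
        if method == "wm":
            return weighted_median(data, n_boot=50, seed=11)
        return mode_estimate(data, weighted=(method == "weighted"),
                             n_boot=50, seed=11)

    base = run(random_dataset)
    stochastic = method in ("wm", "simple", "weighted")
    for c in (2.5, -1.0):
        scaled = dataset_from_arrays(
            random_dataset.beta_exp,
            random_dataset.se_exp,
            c * random_dataset.beta_out,
            abs(c) * random_dataset.se_out,
        )
        est = run(scaled)
        assert est.beta == pytest.approx(c * base.beta, rel=1e-6, abs=1e-9)
        if stochastic and c < 0:
            # bootstrap draws are not sign-coupled; the se only matches in
            # distribution, so compare loosely
            assert est.se == pytest.approx(abs(c) * base.se, rel=0.5)
        else:
            assert est.se == pytest.approx(abs(c) * base.se, rel=1e-6, abs=1e-9)
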