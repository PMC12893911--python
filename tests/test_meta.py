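import numpy as np
import pandas as pd
import pytest

from microrank.errors import (
    CollinearityError,
    InsufficientDataError,
    ValidationError,
)
from microrank.meta import (
    EffectEstimate,
    beta_to_smd,
    binomial_sign_test,
    cohens_d,
    fit_group_effect,
    mixed_country_effect,
    paule_mandel,
    pool_shared_controls,
    shared_control_covariance,
)


class TestFitGroupEffect:
    def test_unadjusted_beta_is_mean_difference(self):
        y = np.array([1, 2, 3, 4, 2, 3, 4, 5], dtype=float)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        est = fit_group_effect(y, g)
        assert est.beta == pytest.approx(1.0)
        assert est.n_control == est.n_case == 4

    def test_collinear_covariate_named(self):
        y = np.arange(10.0)
        g = np.array([0] * 5 + [1] * 5)
        covs = pd.DataFrame({"dup": g.astype(float)})
        with pytest.raises(CollinearityError) as err:
            fit_group_effect(y, g, covs)
        assert err.value.column == "dup"

    def test_recovers_group_effect_with_covariate(self):
        rng = np.random.default_rng(0)
        n = 400
        g = rng.integers(0, 2, n)
        sex = rng.integers(0, 2, n)
        y = 0.5 * g + 0.8 * sex + rng.normal(0, 1, n)
        est = fit_group_effect(y, g, pd.DataFrame({"sex": sex}))
        assert est.beta == pytest.approx(0.5, abs=0.15)

    def test_small_arm_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_group_effect(np.arange(6.0), np.array([0, 0, 0, 1, 1, 1]))


class TestCohensD:
    def test_equal_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == 0.0

    def test_hand_example_pooled_sd_one(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_antisymmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(1, 1, size=20)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestBetaToSmd:
    def test_direct_division(self):
        est = EffectEstimate("d", beta=1.0, se=0.5, n_control=10, n_case=10,
                             outcome_sd=2.0)
        est = beta_to_smd(est)
        assert est.smd == pytest.approx(0.5)
        assert est.smd_se == pytest.approx(0.25)

    def test_zero_beta_zero_smd(self):
        est = beta_to_smd(
            EffectEstimate("d", beta=0.0, se=0.1, n_control=5, n_case=5,
                           outcome_sd=3.0)
        )
        assert est.smd == 0.0

    def test_smd_consistent_with_cohens_d_no_covariates(self):
        rng = np.random.default_rng(3)
        n = 500
        g = np.array([0] * n + [1] * n)
        y = 0.4 * g + rng.normal(size=2 * n)
        est = beta_to_smd(fit_group_effect(y, g))
        d = cohens_d(y[g == 1], y[g == 0])
        assert est.smd == pytest.approx(d, abs=0.1)


class TestPauleMandel:
    def test_homogeneous_studies(self):
        res = paule_mandel([0.5, 0.5], [0.1, 0.1])
        assert res.tau2 == pytest.approx(0.0, abs=1e-8)
        assert res.pooled == pytest.approx(0.5)

    def test_symmetric_heterogeneous_pair(self):
        res = paule_mandel([0.0, 1.0], [0.01, 0.01])
        assert res.tau2 > 0
        assert res.pooled == pytest.approx(0.5)

    def test_equal_variances_tau_zero_reduces_to_mean(self):
        effects = [0.2, 0.25, 0.22, 0.24]
        res = paule_mandel(effects, [0.5] * 4)
        assert res.tau2 == 0.0
        assert res.pooled == pytest.approx(np.mean(effects))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.3, 0.4, size=6)
        v = rng.uniform(0.02, 0.2, size=6)
        base = paule_mandel(y, v)
        shifted = paule_mandel(y + 10, v)
        assert shifted.pooled == pytest.approx(base.pooled + 10, abs=1e-8)
        assert shifted.tau2 == pytest.approx(base.tau2, abs=1e-8)

    def test_grid_search_oracle_fixture(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 0.8, size=5)
        v = rng.uniform(0.01, 0.1, size=5)
        res = paule_mandel(y, v)
        grid = np.arange(0.0, 10.0, 1e-4)
        w = 1.0 / (v[None, :] + grid[:, None])
        ybar = (w * y).sum(1) / w.sum(1)
        crit = (w * (y[None, :] - ybar[:, None]) ** 2).sum(1) - (len(y) - 1)
        tau_grid = 0.0 if crit[0] <= 0 else grid[np.argmin(np.abs(crit))]
        assert res.tau2 == pytest.approx(tau_grid, abs=2e-4)

    def test_agrees_with_statsmodels_pm(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(13)
        y = rng.normal(0.2, 0.5, size=7)
        v = rng.uniform(0.02, 0.15, size=7)
        res = paule_mandel(y, v)
        ref = combine_effects(y, v, method_re="pm")
        assert res.tau2 == pytest.approx(ref.tau2, abs=1e-5)
        assert res.pooled == pytest.approx(ref.mean_effect_re, abs=1e-6)

    def test_single_study_passthrough(self):
        res = paule_mandel([0.7], [0.04])
        assert res.pooled == 0.7
        assert res.tau2 == 0.0
        assert "single study" in res.note


def _estimate(ds, smd, smd_se, n_control=100, n_case=100):
    return EffectEstimate(ds, beta=smd, se=smd_se, n_control=n_control,
                          n_case=n_case, outcome_sd=1.0, smd=smd, smd_se=smd_se)


class TestSharedControlCovariance:
    def test_no_overlap_diagonal(self):
        ests = [_estimate("a", 0.2, 0.1), _estimate("b", 0.3, 0.2)]
        cov = shared_control_covariance(ests)
        assert cov[0, 1] == 0
        assert cov[0, 0] == pytest.approx(0.01)

    def test_zero_effect_overlap_formula(self):
        ests = [_estimate("a", 0.0, 0.1), _estimate("b", 0.0, 0.1)]
        cov = shared_control_covariance(ests, {("a", "b"): 100})
        assert cov[0, 1] == pytest.approx(0.01)

    def test_overlap_exceeding_controls_rejected(self):
        ests = [_estimate("a", 0.0, 0.1, n_control=50), _estimate("b", 0.0, 0.1)]
        with pytest.raises(ValidationError):
            shared_control_covariance(ests, {("a", "b"): 60})

    def test_positive_definite_on_random_fixtures(self):
        # coherent fixtures: the SMD standard error follows from the arm
        # sizes (se^2 = 1/n_case + 1/n_control + smd^2 / (2 n)), as it does
        # for any estimate produced by fit_group_effect + beta_to_smd
        rng = np.random.default_rng(4)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            shared_n0 = int(rng.integers(30, 200))
            share = rng.random() < 0.7
            ests = []
            for i in range(k):
                n0 = shared_n0 if (share and i < 2) else int(rng.integers(30, 200))
                n1 = int(rng.integers(30, 200))
                smd = float(rng.normal(0, 0.5))
                se = float(np.sqrt(1 / n0 + 1 / n1 + smd**2 / (2 * (n0 + n1))))
                ests.append(_estimate(f"d{i}", smd, se, n_control=n0, n_case=n1))
            overlap = {("d0", "d1"): shared_n0} if share else {}
            cov = shared_control_covariance(ests, overlap)
            assert np.linalg.eigvalsh(cov).min() > 0


class TestPoolSharedControls:
    def test_diagonal_reduces_to_inverse_variance_mean(self):
        ests = [_estimate("a", 0.2, 0.1), _estimate("b", 0.6, 0.2)]
        cov = np.diag([0.01, 0.04])
        res = pool_shared_controls(ests, cov)
        w = np.array([1 / 0.01, 1 / 0.04])
        assert res.pooled == pytest.approx((w @ [0.2, 0.6]) / w.sum())
        assert res.se == pytest.approx(w.sum() ** -0.5)

    def test_perfectly_correlated_identical_studies(self):
        ests = [_estimate("a", 0.4, 0.1), _estimate("b", 0.4, 0.1)]
        cov = np.full((2, 2), 0.01)
        cov[np.diag_indices(2)] = 0.01 + 1e-12
        res = pool_shared_controls(ests, cov)
        assert res.pooled == pytest.approx(0.4)
        assert res.se == pytest.approx(0.1, rel=1e-3)

    def test_three_study_matrix_algebra_oracle(self):
        ests = [_estimate("a", 0.2, 0.1), _estimate("b", 0.5, 0.15),
                _estimate("c", 0.3, 0.2)]
        cov = shared_control_covariance(ests, {("a", "b"): 80})
        res = pool_shared_controls(ests, cov)
        y = np.array([0.2, 0.5, 0.3])
        ones = np.ones(3)
        inv = np.linalg.inv(cov)
        assert res.pooled == pytest.approx((ones @ inv @ y) / (ones @ inv @ ones),
                                           abs=1e-10)
        assert res.se == pytest.approx((ones @ inv @ ones) ** -0.5, abs=1e-10)


class TestBinomialSignTest:
    def test_printed_direction_count(self):
        # 34 of 47 pairwise comparisons in the favourable direction
        assert round(binomial_sign_test(34, 47), 3) == 0.003

    def test_all_successes_small_n(self):
        assert binomial_sign_test(5, 5) == pytest.approx(0.0625)

    def test_mode_capped_at_one(self):
        assert binomial_sign_test(4, 8) == 1.0

    def test_one_sided_option(self):
        assert binomial_sign_test(21, 25, alternative="greater") == pytest.approx(
            0.000455, abs=5e-6
        )

    def test_bad_input_rejected(self):
        with pytest.raises(ValidationError):
            binomial_sign_test(5, 4)


class TestMixedCountryEffect:
    def test_matches_ols_when_no_dataset_effects(self):
        rng = np.random.default_rng(6)
        n = 300
        country = rng.integers(0, 2, n)
        ds = np.where(country == 0, rng.integers(0, 2, n), rng.integers(2, 4, n))
        depth = rng.uniform(1e9, 5e9, n)
        y = 0.5 * country + rng.normal(size=n)
        est = mixed_country_effect(y, country, ds, depth)
        assert est.beta == pytest.approx(0.5, abs=2 * est.se)

    def test_falls_back_to_ols_with_single_datasets(self):
        rng = np.random.default_rng(7)
        n = 100
        country = np.array([0] * 50 + [1] * 50)
        ds = np.where(country == 0, "d0", "d1")
        y = 0.3 * country + rng.normal(size=n)
        est = mixed_country_effect(y, country, ds, rng.uniform(1e9, 5e9, n))
        assert "OLS fallback" in est.note

    def test_mixed_model_less_biased_than_ols_under_dataset_confounding(self):
        import statsmodels.api as sm

        bias_mixed, bias_ols = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            # two datasets per country with strong dataset intercepts that
            # partially confound the (null) country effect
            ds_effects = rng.normal(0, 1.0, size=4)
            ds = rng.integers(0, 4, 400)
            country = (ds >= 2).astype(int)
            depth = rng.uniform(1e9, 5e9, 400)
            y = ds_effects[ds] + rng.normal(0, 1, 400)
            est = mixed_country_effect(y, country, ds, depth)
            X = sm.add_constant(np.column_stack([country, (depth - depth.mean())
                                                 / depth.std()]))
            ols = sm.OLS(y, X).fit()
            bias_mixed.append(abs(est.beta))
            bias_ols.append(abs(ols.params[1]))
        assert np.mean(bias_mixed) <= np.mean(bias_ols) + 0.05
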