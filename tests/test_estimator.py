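import numpy as np
import pytest
from scipy.stats import multivariate_normal

import mlgmsim as m
from mlgmsim.estimator import (
    LinearCodec,
    TemplateCodec,
    fit,
    loglik_and_grad,
    start_values,
)
from mlgmsim.model_spec import get_template


def _random_psd(rng, n, scale=1.0):
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))


class TestLoglikOracle:
    def test_matches_bruteforce_on_random_small_instances(self, spec):
        """Sufficient-statistic likelihood == exact Kronecker density, 50 cases."""
        rng = np.random.default_rng(2024)
        mom = m.implied_moments(spec)
        for k in range(50):
            ng = int(rng.integers(1, 5)) * 2
            small = int(rng.integers(1, 4))
            cond = m.DesignCondition(ng, small, 3 * small)
            ds = m.simulate_dataset(spec, cond, int(rng.integers(1 << 30)))
            # random admissible parameter values, not just the truth
            sw = _random_psd(rng, 5, 10.0)
            sb = _random_psd(rng, 5, 2.0)
            mu = mom.mean + rng.standard_normal(5)
            fast = m.loglik_moments(sw, sb, mu, m.sufficient_stats(ds))
            brute = m.loglik_bruteforce(sw, sb, mu, ds)
            assert fast == pytest.approx(brute, abs=1e-8), f"case {k}"

    def test_single_cluster_of_one_is_total_covariance_density(self, spec):
        mom = m.implied_moments(spec)
        y = np.array([[50.0, 54.0, 58.0, 62.0, 65.0]])
        ds = m.ClusteredDataset(np.array([1]), np.array([1]), y)
        ll = m.loglik_moments(
            mom.within_cov, mom.between_cov, mom.mean, m.sufficient_stats(ds)
        )
        direct = multivariate_normal.logpdf(y[0], mom.mean, mom.within_cov + mom.between_cov)
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_doubling_clusters_doubles_loglik(self, spec, tiny_dataset):
        mom = m.implied_moments(spec)
        ds = tiny_dataset
        doubled = m.ClusteredDataset(
            np.concatenate([ds.cluster_ids, ds.cluster_ids + ds.cluster_ids.max()]),
            np.concatenate([ds.member_ids, ds.member_ids]),
            np.vstack([ds.y, ds.y]),
        )
        ll1 = m.loglik_moments(mom.within_cov, mom.between_cov, mom.mean, m.sufficient_stats(ds))
        ll2 = m.loglik_moments(
            mom.within_cov, mom.between_cov, mom.mean, m.sufficient_stats(doubled)
        )
        assert ll2 == pytest.approx(2 * ll1, abs=1e-8)

    def test_zero_between_reduces_to_independent_rows(self, spec, tiny_dataset):
        mom = m.implied_moments(spec)
        ll = m.loglik_bruteforce(mom.within_cov, np.zeros((5, 5)), mom.mean, tiny_dataset)
        direct = multivariate_normal.logpdf(tiny_dataset.y, mom.mean, mom.within_cov).sum()
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_member_permutation_invariance(self, spec, tiny_dataset):
        mom = m.implied_moments(spec)
        rng = np.random.default_rng(5)
        order = np.concatenate(
            [rng.permutation(np.flatnonzero(tiny_dataset.cluster_ids == g)) for g in [1, 2, 3, 4]]
        )
        shuffled = m.ClusteredDataset(
            tiny_dataset.cluster_ids[order], tiny_dataset.member_ids, tiny_dataset.y[order]
        )
        a = m.loglik_bruteforce(mom.within_cov, mom.between_cov, mom.mean, tiny_dataset)
        b = m.loglik_bruteforce(mom.within_cov, mom.between_cov, mom.mean, shuffled)
        assert a == pytest.approx(b, abs=1e-8)


class TestGradients:
    @pytest.mark.parametrize("name", ["H1", "PS_B", "PS_W", "BASE_MEAN"])
    def test_analytic_gradient_matches_finite_differences(self, spec, tiny_dataset, name):
        stats = m.sufficient_stats(tiny_dataset)
        codec = TemplateCodec(get_template(name), spec.basis)
        x0 = start_values(get_template(name), stats, spec.basis)
        _, g = loglik_and_grad(x0, stats, codec)
        eps = 1e-6
        for i in range(0, len(x0), 3):  # spot-check every third coordinate
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            num = (
                m.loglik_moments(*codec.decode(xp)[:3], stats)
                - m.loglik_moments(*codec.decode(xm)[:3], stats)
            ) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestStartValues:
    def test_residual_floor_applied(self, basis):
        zero_theta = m.LevelParams(np.zeros(3), np.eye(3), np.zeros(5))
        between = m.LevelParams(np.ones(3), np.eye(3), np.zeros(5))
        spec0 = m.MLGMSpec(basis=basis, within=zero_theta, between=between)
        ds = m.simulate_dataset(spec0, m.DesignCondition(20, 5, 15), seed=4)
        stats = m.sufficient_stats(ds)
        codec = LinearCodec(get_template("PS_B"), basis)
        x0 = codec.encode(*__import__("mlgmsim.estimator", fromlist=["_moment_starts"])._moment_starts(stats))
        _, s2, _ = codec.slices
        theta_start = x0[s2][-5:]
        assert np.all(theta_start >= 1e-4 - 1e-12)

    def test_saturated_start_reproduces_pooled_within(self, spec, tiny_dataset):
        stats = m.sufficient_stats(tiny_dataset)
        codec = LinearCodec(get_template("H1"), spec.basis)
        from mlgmsim.estimator import start_values_linear

        sw, _, _ = codec.decode(start_values_linear(codec, stats))
        np.testing.assert_allclose(sw, m.pooled_within_cov(tiny_dataset), atol=1e-10)

    def test_between_start_near_truth_in_large_balanced_sample(self, spec):
        ds = m.simulate_dataset(spec, m.DesignCondition(3000, 30, 30), seed=6)
        stats = m.sufficient_stats(ds)
        from mlgmsim.estimator import _moment_starts

        _, sb0, _ = _moment_starts(stats)
        truth = m.implied_moments(spec).between_cov
        np.testing.assert_allclose(np.diag(sb0), np.diag(truth), rtol=0.10)


class TestFit:
    def test_ascent_over_start_values(self, spec, tiny_dataset):
        stats = m.sufficient_stats(tiny_dataset)
        tpl = get_template("H1")
        codec = TemplateCodec(tpl, spec.basis)
        x0 = start_values(tpl, stats, spec.basis)
        ll0 = m.loglik_moments(*codec.decode(x0)[:3], stats)
        res = fit(tpl, stats, spec.basis)
        assert res.loglik >= ll0 - 1e-9

    def test_balanced_saturated_fit_has_closed_form(self, spec):
        """Balanced designs admit an exact ML solution for the saturated model:
        Sigma_W = pooled scatter / (N - G), V = between scatter / G."""
        n = 10
        ds = m.simulate_dataset(spec, m.DesignCondition(100, n, n), seed=17)
        stats = m.sufficient_stats(ds)
        res = fit(get_template("H1"), stats, spec.basis, m.OptimOptions(tol=1e-9))
        assert res.converged
        N, G = stats.n_total, stats.n_groups
        sw_exact = stats.pooled_within_scatter / (N - G)
        ybar = stats.grand_mean()
        cls = stats.size_classes[0]
        v_exact = (cls.scatter + cls.count * np.outer(cls.mean - ybar, cls.mean - ybar)) / G
        ll_closed = m.loglik_moments(sw_exact, v_exact - sw_exact / n, ybar, stats)
        assert res.loglik == pytest.approx(ll_closed, abs=1e-6)
        np.testing.assert_allclose(res.params["sigma_w"], sw_exact, atol=1e-3)
        np.testing.assert_allclose(res.params["sigma_b"], v_exact - sw_exact / n, atol=1e-3)
        np.testing.assert_allclose(res.params["mu"], ybar, atol=1e-8)

    def test_translation_invariance(self, spec):
        ds = m.simulate_dataset(spec, m.DesignCondition(30, 5, 15), seed=23)
        shift = np.array([1.0, -2.0, 3.0, 0.5, -1.5])
        shifted = m.ClusteredDataset(ds.cluster_ids, ds.member_ids, ds.y + shift)
        opts = m.OptimOptions(tol=1e-9)
        for name in ("H1", "PS_B"):
            a = fit(get_template(name), m.sufficient_stats(ds), spec.basis, opts)
            b = fit(get_template(name), m.sufficient_stats(shifted), spec.basis, opts)
            np.testing.assert_allclose(b.params["mu"], a.params["mu"] + shift, atol=1e-5)
            np.testing.assert_allclose(b.params["sigma_w"], a.params["sigma_w"], atol=1e-5)
            np.testing.assert_allclose(b.params["sigma_b"], a.params["sigma_b"], atol=1e-5)
            assert 2 * (b.loglik - a.loglik) == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_within_level(self, spec):
        ests = []
        for r in range(5):
            ds = m.simulate_dataset(spec, m.DesignCondition(200, 25, 75), seed=600 + r)
            res = fit(get_template("PS_W"), m.sufficient_stats(ds), spec.basis)
            assert res.converged
            ests.append(res.params["phi_w"][0, 0])
        assert np.mean(ests) == pytest.approx(71.45, rel=0.05)


class TestCatalog:
    def test_nesting_monotonicity(self, fitted_catalog):
        _, _, fits = fitted_catalog
        h1 = fits["H1"].loglik
        for name, res in fits.items():
            assert res.loglik <= h1 + 1e-6, name
        assert fits["PS_B"].loglik >= fits["BASE_B"].loglik
        assert fits["PS_W"].loglik >= fits["BASE_W"].loglik
        assert fits["TS_MEAN"].loglik >= fits["BASE_MEAN"].loglik

    def test_literal_ts_cov_aliases_ps_b(self, fitted_catalog):
        _, _, fits = fitted_catalog
        assert fits["TS_COV"].loglik == fits["PS_B"].loglik
        assert fits["TS_COV"].n_free == fits["PS_B"].n_free

    def test_all_templates_converge_on_study_data(self, fitted_catalog):
        _, _, fits = fitted_catalog
        assert all(res.converged for res in fits.values())
        assert all(np.isfinite(res.loglik) for res in fits.values())

    def test_fitted_solution_is_local_max_of_bruteforce(self, spec, tiny_dataset):
        """The fast-likelihood optimum is a local max of the exact density."""
        stats = m.sufficient_stats(tiny_dataset)
        res = fit(get_template("H1"), stats, spec.basis, m.OptimOptions(tol=1e-9))
        sw, sb, mu = res.params["sigma_w"], res.params["sigma_b"], res.params["mu"]
        ll_hat = m.loglik_bruteforce(sw, sb, mu, tiny_dataset)
        assert ll_hat == pytest.approx(res.loglik, abs=1e-8)
        rng = np.random.default_rng(0)
        for _ in range(20):
            d_mu = 1e-3 * rng.standard_normal(5)
            e = 1e-3 * rng.standard_normal((5, 5))
            d_sw = e + e.T
            perturbed = m.loglik_bruteforce(sw + d_sw, sb, mu + d_mu, tiny_dataset)
            assert perturbed <= ll_hat + 1e-7
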