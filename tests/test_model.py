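"""Prior construction, the variational fit, and purification."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from blade import (
    BulkMatrix,
    FitOptions,
    build_prior,
    fit,
    purify_group,
    purify_high_resolution,
    simulate_dataset,
)

CONFIG = {"alpha": 1.0, "alpha0": 1.0, "kappa0": 1.0, "s": 1.0}


def _bulk(seed=0, J=6, I=4):
    rng = np.random.default_rng(seed)
    return BulkMatrix(
        rng.lognormal(0, 1, size=(J, I)),
        [f"g{j}" for j in range(J)],
        [f"s{i}" for i in range(I)],
    )


class TestBuildPrior:
    def test_beta0_and_passthrough_arithmetic(self):
        """beta0 = alpha0 * sd^2; alpha/kappa0 copied from the config."""
        bulk = _bulk()
        sd = np.full((6, 2), 0.5)
        prior = build_prior(np.zeros((6, 2)), sd, bulk, CONFIG)
        np.testing.assert_allclose(prior.beta0, 0.25)
        prior5 = build_prior(np.zeros((6, 2)), np.full((6, 2), 2.0), bulk,
                             {"alpha": 3.0, "alpha0": 5.0, "kappa0": 0.7, "s": 1.0})
        np.testing.assert_allclose(prior5.beta0, 20.0)
        assert prior5.dirichlet_alpha == 3.0 and prior5.kappa0 == 0.7

    def test_gamma_is_inverse_scaled_log_variance(self):
        """gamma_j = 1 / (Var_j(log y) * s), checked against direct recomputation."""
        bulk = _bulk(seed=3)
        for s in (1.0, 0.3):
            prior = build_prior(np.zeros((6, 2)), np.full((6, 2), 0.5), bulk,
                                {**CONFIG, "s": s})
            var = np.log(bulk.values).var(axis=1, ddof=0)
            np.testing.assert_allclose(prior.gamma, 1.0 / (var * s))

    def test_gene_mismatch_raises(self):
        bulk = _bulk()
        with pytest.raises(KeyError):
            build_prior(np.zeros((6, 2)), np.full((6, 2), 0.5), bulk, CONFIG,
                        gene_ids=[f"other{j}" for j in range(6)])

    def test_zero_variance_gene_floored_with_warning(self):
        values = np.ones((3, 4))  # every gene constant across samples
        values[1:] = np.random.default_rng(0).lognormal(0, 1, size=(2, 4))
        bulk = BulkMatrix(values, ["g0", "g1", "g2"], list("abcd"))
        with pytest.warns(UserWarning, match="zero across-sample"):
            prior = build_prior(np.zeros((3, 2)), np.full((3, 2), 0.5), bulk, CONFIG)
        assert np.all(np.isfinite(prior.gamma)) and np.all(prior.gamma > 0)

    def test_sd_floor_avoids_improper_prior(self):
        bulk = _bulk()
        sd = np.zeros((6, 2))
        prior = build_prior(np.zeros((6, 2)), sd, bulk, CONFIG)
        assert np.all(prior.beta0 > 0)


class TestFit:
    def test_single_type_fractions_are_one(self):
        ds = simulate_dataset(I=3, J=8, T=1, sigma=0.3, seed=0)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.3), ds.bulk, CONFIG)
        res = fit(ds.bulk, prior, FitOptions(max_iter=200))
        np.testing.assert_allclose(res.fractions, 1.0)

    def test_recovery_with_true_prior(self):
        """With the generating signature as prior, fractions are recovered."""
        ds = simulate_dataset(I=10, J=100, T=3, sigma=0.1, seed=42)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.1), ds.bulk, CONFIG)
        res = fit(ds.bulk, prior, FitOptions(seed=0))
        r = pearsonr(ds.true_fractions.ravel(), res.fractions.ravel())[0]
        assert r >= 0.9
        assert res.converged

    def test_trace_non_increasing_and_simplex(self):
        ds = simulate_dataset(I=5, J=30, T=3, sigma=0.5, seed=7)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.5), ds.bulk, CONFIG)
        res = fit(ds.bulk, prior, FitOptions(seed=0))
        assert np.all(np.diff(res.objective_trace) <= 1e-8)
        assert np.all(res.fractions >= 0)
        np.testing.assert_allclose(res.fractions.sum(axis=1), 1.0, atol=1e-8)

    def test_sample_permutation_equivariance(self):
        """Permuting bulk columns permutes fraction rows identically."""
        ds = simulate_dataset(I=5, J=40, T=3, sigma=0.3, seed=3)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.3), ds.bulk, CONFIG)
        res = fit(ds.bulk, prior, FitOptions(seed=0))
        perm = [3, 0, 4, 1, 2]
        bulk_p = BulkMatrix(ds.bulk.values[:, perm], ds.bulk.gene_ids,
                            [ds.bulk.sample_ids[i] for i in perm])
        res_p = fit(bulk_p, prior, FitOptions(seed=0))
        np.testing.assert_allclose(res_p.fractions, res.fractions[perm], atol=1e-4)

    def test_scale_equivariance_other_samples(self):
        """Rescaling one sample's bulk barely moves other samples' fractions.

        The likelihood separates across samples, but the collapsed
        normal-gamma block shares (mu, lambda) across samples, so a rescaled
        sample shifts the learned within-type variance for everyone: the
        invariance is approximate, with drift growing with |log c|.  A 25%
        rescale must stay within 0.02 absolute on other samples' fractions.
        """
        ds = simulate_dataset(I=6, J=60, T=3, sigma=0.3, seed=9)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.3), ds.bulk, CONFIG)
        res = fit(ds.bulk, prior, FitOptions(seed=0))
        values = ds.bulk.values.copy()
        values[:, 2] *= 1.25
        bulk2 = BulkMatrix(values, ds.bulk.gene_ids, ds.bulk.sample_ids)
        res2 = fit(bulk2, prior, FitOptions(seed=0))
        others = [i for i in range(6) if i != 2]
        assert np.max(np.abs(res2.fractions[others] - res.fractions[others])) < 0.02

    def test_nan_input_raises(self):
        ds = simulate_dataset(I=3, J=10, T=2, sigma=0.3, seed=0)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.3), ds.bulk, CONFIG)
        values = ds.bulk.values.copy()
        values[0, 0] = np.nan
        with pytest.raises(ValueError):
            bad = BulkMatrix.__new__(BulkMatrix)
            bad.values, bad.gene_ids, bad.sample_ids, bad.scale = (
                values, ds.bulk.gene_ids, ds.bulk.sample_ids, "linear")
            fit(bad, prior)

    def test_underdetermined_warns(self):
        ds = simulate_dataset(I=3, J=2, T=4, sigma=0.3, seed=0)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.3), ds.bulk, CONFIG)
        with pytest.warns(UserWarning, match="underdetermined"):
            fit(ds.bulk, prior, FitOptions(max_iter=50))


class TestPurify:
    def _result(self):
        ds = simulate_dataset(I=4, J=20, T=2, sigma=0.2, seed=5)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.2), ds.bulk, CONFIG)
        return fit(ds.bulk, prior, FitOptions(seed=0))

    def test_posterior_mean_closed_form(self):
        """exp(nu + omega/2): nu=0, omega->0 gives 1; nu=log 2 gives 2."""
        res = self._result()
        res.state.nu[:] = 0.0
        res.state.omega[:] = 1e-300
        np.testing.assert_allclose(purify_high_resolution(res), 1.0)
        res.state.nu[:] = np.log(2.0)
        np.testing.assert_allclose(purify_high_resolution(res), 2.0)

    def test_strictly_positive(self):
        assert np.all(purify_high_resolution(self._result()) > 0)

    def test_group_is_mean_over_samples(self):
        res = self._result()
        np.testing.assert_allclose(
            purify_group(res), purify_high_resolution(res).mean(axis=0)
        )

    def test_group_single_sample_identity(self):
        ds = simulate_dataset(I=1, J=15, T=2, sigma=0.2, seed=6)
        prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, 0.2), ds.bulk, CONFIG)
        res = fit(ds.bulk, prior, FitOptions(seed=0, max_iter=300))
        np.testing.assert_allclose(purify_group(res), purify_high_resolution(res)[0])


def test_recovery_degrades_monotonically_with_noise():
    """Mean fraction correlation falls as within-type variability grows.

    Means over 3 seeds at sigma in {0.1, 0.5, 1.0, 1.5} on 10 x 100 x 5
    cohorts with the true signature as prior must be non-increasing (small
    slack for seed noise) and start above 0.9.
    """
    from scipy.stats import pearsonr

    means = []
    for sigma in (0.1, 0.5, 1.0, 1.5):
        rs = []
        for seed in range(3):
            ds = simulate_dataset(I=10, J=100, T=5, sigma=sigma, seed=seed)
            prior = build_prior(ds.true_mu, np.full_like(ds.true_mu, sigma),
                                ds.bulk, CONFIG)
            res = fit(ds.bulk, prior, FitOptions(seed=seed))
            rs.append(pearsonr(ds.true_fractions.ravel(), res.fractions.ravel())[0])
        means.append(np.mean(rs))
    assert means[0] >= 0.9
    assert all(means[k + 1] <= means[k] + 0.02 for k in range(3)), means
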