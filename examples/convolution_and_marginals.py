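"""The generic convolution model and marginal distribution comparison.

A bulk observation with known fractions is a weighted sum of per-type
log-normals; the Fenton-Wilkinson (FW) approximation replaces that sum by a
single moment-matched log-normal.  This script quantifies the FW error
against Monte Carlo, recovers planted convolution parameters by maximum
likelihood, and compares marginal families on skewed data.
"""

import numpy as np
from scipy.stats import lognorm

from blade import (
    fit_convolution, fit_marginal, fw_lognormal_params, ln_convolution_draws,
)
from blade.convolution import ConvolutionParams

params = ConvolutionParams(mu=[0.0, 1.0], sigma=[0.3, 0.3], fractions=[[0.5, 0.5]])
draws = ln_convolution_draws(params, 0, 1_000_000, seed=0)
m, s = fw_lognormal_params(params.mu, params.sigma, params.fractions[0])
draws.sort()
ecdf = np.arange(1, draws.size + 1) / draws.size
sup = np.max(np.abs(ecdf - lognorm.cdf(draws, s, scale=np.exp(m))))
print(f"FW vs Monte-Carlo CDF sup-distance: {sup:.4f} (closed form vs 1e6 draws)")

rng = np.random.default_rng(0)
f = rng.dirichlet(np.ones(2), size=200)
x = rng.lognormal([0.0, 2.0], 0.4, size=(200, 2))
est, info = fit_convolution(np.sum(f * x, axis=1), f, seed=0)
print(f"planted mu = (0, 2): recovered {np.sort(est.mu).round(3)}; "
      f"sigma = 0.4: recovered {est.sigma[np.argsort(est.mu)].round(3)}")
print(f"loglik = {info['loglik']:.1f} with {info['n_params']} free parameters")

xs = rng.lognormal(0.0, 0.8, 5000)
ln, no = fit_marginal(xs, "lognormal"), fit_marginal(xs, "normal")
print(f"marginal fits on LN(0, 0.8) draws: lognormal loglik {ln.loglik:.0f} "
      f"vs normal {no.loglik:.0f}")
print("The skewed data rewards the log-normal family; the normal fit chases")
print("outliers and misplaces the mode.")
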