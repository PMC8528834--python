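"""Deconvolve a simulated bulk cohort with a known signature.

Simulates 20 bulk samples mixing 5 cell types over 200 genes at a moderate
within-type variability (log-SD 0.5), fits the model with the generating
signature as prior, and scores fractions against the ground truth and the
NNLS baseline.
"""

import numpy as np
from scipy.stats import pearsonr

from blade import (
    FitOptions, build_prior, fit, nnls_baseline, score_fractions, simulate_dataset,
)

ds = simulate_dataset(I=20, J=200, T=5, sigma=0.5, seed=0)
prior = build_prior(
    ds.true_mu, np.full_like(ds.true_mu, 0.5), ds.bulk,
    {"alpha": 1.0, "alpha0": 1.0, "kappa0": 1.0, "s": 1.0},
)
result = fit(ds.bulk, prior, FitOptions(seed=0))

report = score_fractions(ds.true_fractions, result.fractions, ds.cell_types)
base = nnls_baseline(ds.bulk, prior.mu0)
base_r = pearsonr(ds.true_fractions.ravel(), base.ravel())[0]

print(report.per_type.round(3).to_string(index=False))
print(f"pooled Pearson r = {report.overall['pearson']:.3f}, "
      f"RMSE = {report.overall['rmse']:.4f}")
print(f"NNLS baseline pooled r = {base_r:.3f}")
print("Per-type rows: correlation between true and estimated fractions across")
print("samples; the pooled row flattens all (sample, type) pairs. The Bayesian")
print("fit should beat NNLS at this noise level.")
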