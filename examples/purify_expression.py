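"""In silico purification: recover per-type expression from bulk mixtures.

After the joint fit, the posterior mean of each purified expression value
exp(nu + omega/2) gives one profile per (sample, gene, type) — the
high-resolution mode — and averaging over samples gives the group mode.
Correlations are computed on the log scale.
"""

import numpy as np

from blade import (
    FitOptions, build_prior, fit, purify_group, purify_high_resolution,
    score_purification, simulate_dataset,
)

ds = simulate_dataset(I=20, J=200, T=5, sigma=0.1, seed=1)
prior = build_prior(
    ds.true_mu, np.full_like(ds.true_mu, 0.1), ds.bulk,
    {"alpha": 1.0, "alpha0": 1.0, "kappa0": 1.0, "s": 1.0},
)
result = fit(ds.bulk, prior, FitOptions(seed=0))

group = score_purification(ds.true_x.mean(axis=0), purify_group(result), "group")
print("group mode (per type, across genes):")
print(group.per_type[["cell_type", "pearson"]].round(4).to_string(index=False))

high = score_purification(ds.true_x, purify_high_resolution(result), "highres")
pairs = high.overall["per_pair"]
print(f"high-resolution mode: {len(pairs)} (type, sample) profiles, "
      f"mean r = {high.overall['pearson']:.4f}, "
      f"all finite: {pairs['pearson'].notna().all()}")
print("Every gene receives an estimate in both modes; no gene is filtered.")
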