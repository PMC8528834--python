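"""Empirical-Bayes hyperparameter selection.

The model exposes four user-set scalars: the Dirichlet pseudo-count ``alpha``,
the normal-gamma shape ``alpha0`` (how much the single-cell signature is
trusted), the prior-mean scale ``kappa0``, and the observation-noise scale
``s``.  Selection is by exhaustive grid search: every configuration is fitted
on one shared random subset of samples, the configuration with the highest
converged bound (the tractable marginal-likelihood surrogate) wins, and a
full-data fit is run under the winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FitOptions, build_prior, fit
from .types import BulkMatrix, FitResult

__all__ = [
    "HyperparameterGrid",
    "default_grid",
    "default_subset_size",
    "select_configuration",
    "run_empirical_bayes",
]

_PARAM_NAMES = ("alpha", "alpha0", "kappa0", "s")


@dataclass
class HyperparameterGrid:
    """Cartesian product of candidate values for the four shared scalars."""

    alpha_candidates: Sequence[float] = (1.0, 10.0)
    alpha0_candidates: Sequence[float] = (0.1, 0.5, 1.0, 5.0, 10.0)
    kappa0_candidates: Sequence[float] = (1.0, 0.5, 0.1)
    s_candidates: Sequence[float] = (1.0, 0.3, 0.5)
    configurations: list = field(init=False)

    def __post_init__(self) -> None:
        for name in ("alpha_candidates", "alpha0_candidates",
                     "kappa0_candidates", "s_candidates"):
            vals = list(getattr(self, name))
            if not vals or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be non-empty and positive")
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate values in {name}")
        self.configurations = [
            dict(zip(_PARAM_NAMES, combo))
            for combo in product(
                self.alpha_candidates,
                self.alpha0_candidates,
                self.kappa0_candidates,
                self.s_candidates,
            )
        ]

    def __len__(self) -> int:
        return len(self.configurations)


def default_grid() -> HyperparameterGrid:
    """The 90-configuration default grid (2 x 5 x 3 x 3)."""
    return HyperparameterGrid()


def default_subset_size(n_samples: int) -> int:
    """Subset size for configuration scoring: min(10, ceil(I / 2))."""
    return min(10, int(np.ceil(n_samples / 2)))


def _subset_bulk(bulk: BulkMatrix, idx: np.ndarray) -> BulkMatrix:
    return BulkMatrix(
        bulk.values[:, idx],
        bulk.gene_ids,
        [bulk.sample_ids[i] for i in idx],
        bulk.scale,
    )


def select_configuration(
    bulk: BulkMatrix,
    signature_mean: np.ndarray,
    signature_sd: np.ndarray,
    grid: HyperparameterGrid | None = None,
    subset_size: int | None = None,
    seed: int = 0,
    opts: FitOptions | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Score every grid configuration on one shared sample subset.

    Returns the winning configuration (ties broken by grid order) and the
    full score table (one row per configuration, in grid order, with the
    converged ELBO as the score).  Deterministic given ``seed``.
    """
    grid = grid or default_grid()
    I = bulk.n_samples
    subset_size = default_subset_size(I) if subset_size is None else subset_size
    if not 1 <= subset_size <= I:
        raise ValueError(f"subset_size must be in [1, {I}], got {subset_size}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(I, size=subset_size, replace=False))
    sub = _subset_bulk(bulk, idx)
    opts = opts or FitOptions(seed=seed)

    rows = []
    for k, config in enumerate(grid.configurations):
        row = {"config_index": k, **config}
        try:
            prior = build_prior(signature_mean, signature_sd, sub, config)
            res = fit(sub, prior, opts)
            row["elbo"] = -res.config["neg_elbo"]
            row["converged"] = res.converged
        except (RuntimeError, FloatingPointError) as exc:
            row["elbo"] = np.nan
            row["converged"] = False
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    scores = table["elbo"].to_numpy()
    if np.all(np.isnan(scores)):
        raise RuntimeError(
            f"no hyperparameter configuration converged; score table:\n{table}"
        )
    best_idx = int(np.nanargmax(scores))   # first max wins on ties
    return dict(grid.configurations[best_idx]), table


def run_empirical_bayes(
    bulk: BulkMatrix,
    signature_mean: np.ndarray,
    signature_sd: np.ndarray,
    grid: HyperparameterGrid | None = None,
    subset_size: int | None = None,
    seed: int = 0,
    opts: FitOptions | None = None,
) -> FitResult:
    """Select a configuration on a subset, then fit the full data under it."""
    config, table = select_configuration(
        bulk, signature_mean, signature_sd, grid, subset_size, seed, opts
    )
    prior = build_prior(signature_mean, signature_sd, bulk, config)
    result = fit(bulk, prior, opts or FitOptions(seed=seed))
    result.config["score_table"] = table
    return result
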