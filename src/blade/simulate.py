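"""Data generators: parametric log-normal mixtures, the full simulation grid,
a negative-binomial labelled single-cell generator, and pseudo-bulk mixing.

The parametric generator draws, per gene ``j`` and cell type ``t``, an expected
log expression ``mu_jt ~ N(0, mu_sd**2)``; per sample it draws purified
expression ``log x_ijt ~ N(mu_jt, sigma**2)`` and fractions
``f_i ~ Dirichlet(1, ..., 1)``; the bulk is the noise-free mixture
``y_ij = sum_t f_i^t x_ij^t``.  ``sigma`` is the controlled within-type
expression variability (log-scale SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .types import BulkMatrix

__all__ = [
    "SimulatedDataset",
    "SimulationGridSpec",
    "SyntheticSCData",
    "simulate_dataset",
    "enumerate_grid",
    "generate_synthetic_sc",
    "simulate_pseudobulk",
]

#: default SD of the per-(gene, type) expected log expression
DEFAULT_MU_SD = 1.5


@dataclass
class SimulatedDataset:
    """Bulk matrix plus the ground truth that produced it."""

    bulk: BulkMatrix
    true_fractions: np.ndarray      # (I, T)
    true_x: np.ndarray              # (I, J, T), linear scale
    true_mu: np.ndarray             # (J, T), log scale
    sigma: float
    seed: int
    cell_types: Sequence[str] = field(default_factory=list)


@dataclass
class SimulationGridSpec:
    """Axis levels of the simulation study grid."""

    n_samples_levels: Sequence[int] = (5, 10, 20, 50, 100)
    n_genes_levels: Sequence[int] = (100, 200, 500, 1000)
    n_types_levels: Sequence[int] = (2, 3, 5, 10, 20)
    sigma_levels: Sequence[float] = (0.1, 0.2, 0.5, 0.75, 1.0, 1.25, 1.5)

    def __post_init__(self) -> None:
        for name in ("n_samples_levels", "n_genes_levels", "n_types_levels", "sigma_levels"):
            levels = getattr(self, name)
            if len(levels) == 0 or any(v <= 0 for v in levels):
                raise ValueError(f"{name} must be non-empty and positive")


@dataclass
class SyntheticSCData:
    """Labelled single-cell counts with known per-type means and planted DEGs."""

    counts: np.ndarray              # (J, n_cells), integer
    labels: np.ndarray              # (n_cells,), type names
    type_means: np.ndarray          # (J, T), expected counts
    cell_types: Sequence[str] = field(default_factory=list)
    gene_ids: Sequence[str] = field(default_factory=list)
    planted_degs: dict = field(default_factory=dict)


def simulate_dataset(
    I: int,
    J: int,
    T: int,
    sigma: float,
    mu_sd: float = DEFAULT_MU_SD,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a bulk cohort with controlled within-type variability.

    Parameters
    ----------
    I, J, T
        Numbers of samples, genes and cell types (all >= 1).
    sigma
        Log-scale SD of purified expression around its per-(gene, type)
        mean; ``sigma = 0`` degenerates to identical expression across
        samples.
    mu_sd
        SD of the per-(gene, type) expected log expression.
    """
    if min(I, J, T) < 1:
        raise ValueError("I, J, T must all be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not mu_sd > 0:
        raise ValueError("mu_sd must be positive")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, mu_sd, size=(J, T))
    logx = rng.normal(mu[None], sigma, size=(I, J, T))
    x = np.exp(logx)
    f = rng.dirichlet(np.ones(T), size=I)
    y = np.einsum("it,ijt->ij", f, x)               # (I, J)
    bulk = BulkMatrix(
        y.T,
        [f"gene{j}" for j in range(J)],
        [f"sample{i}" for i in range(I)],
        "linear",
    )
    return SimulatedDataset(
        bulk=bulk,
        true_fractions=f,
        true_x=x,
        true_mu=mu,
        sigma=float(sigma),
        seed=seed,
        cell_types=[f"type{t}" for t in range(T)],
    )


def enumerate_grid(spec: SimulationGridSpec | None = None) -> list[tuple[int, int, int, float]]:
    """All (I, J, T, sigma) combinations of the simulation study, samples-major."""
    spec = spec or SimulationGridSpec()
    return list(
        product(
            spec.n_samples_levels,
            spec.n_genes_levels,
            spec.n_types_levels,
            spec.sigma_levels,
        )
    )


def generate_synthetic_sc(
    J: int = 1000,
    T: int = 5,
    cells_per_type: int = 200,
    libsize: int = 5000,
    dispersion: float = 0.3,
    n_deg_per_type: int = 25,
    effect_size: float = 2.0,
    seed: int = 0,
) -> SyntheticSCData:
    """Synthetic labelled single-cell counts with planted marker genes.

    Each cell type upregulates a disjoint block of ``n_deg_per_type`` genes by
    ``effect_size`` on the natural-log scale relative to a shared baseline.
    Counts are negative-binomial around library-size-scaled expected
    proportions, with variance ``m + dispersion * m**2``.
    """
    for name, v in (("J", J), ("T", T), ("cells_per_type", cells_per_type),
                    ("libsize", libsize), ("n_deg_per_type", n_deg_per_type)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if dispersion <= 0 or effect_size < 0:
        raise ValueError("dispersion must be positive and effect_size non-negative")
    if T * n_deg_per_type > J:
        raise ValueError("need J >= T * n_deg_per_type for disjoint planted DEG blocks")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(0.0, 1.0, size=J))     # shared relative expression
    rel = np.tile(base[:, None], (1, T))
    planted: dict[str, list[str]] = {}
    gene_ids = [f"gene{j}" for j in range(J)]
    cell_types = [f"type{t}" for t in range(T)]
    for t in range(T):
        idx = np.arange(t * n_deg_per_type, (t + 1) * n_deg_per_type)
        rel[idx, t] *= np.exp(effect_size)
        planted[cell_types[t]] = [gene_ids[j] for j in idx]
    prob = rel / rel.sum(axis=0, keepdims=True)
    mean = prob * libsize                            # (J, T) expected counts

    n_cells = T * cells_per_type
    counts = np.empty((J, n_cells), dtype=np.int64)
    labels = np.empty(n_cells, dtype=object)
    r = 1.0 / dispersion                             # NB size parameter
    for t in range(T):
        m = mean[:, t]
        p = r / (r + m)
        block = rng.negative_binomial(
            r, p[:, None], size=(J, cells_per_type)
        )
        sl = slice(t * cells_per_type, (t + 1) * cells_per_type)
        counts[:, sl] = block
        labels[sl] = cell_types[t]
    return SyntheticSCData(
        counts=counts,
        labels=np.asarray(labels),
        type_means=mean,
        cell_types=cell_types,
        gene_ids=gene_ids,
        planted_degs=planted,
    )


def _apportion(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with a floor of one per type.

    Largest-remainder apportionment of ``total - T`` cells on top of the
    mandatory one cell per type; deterministic given the fractions.
    """
    T = fractions.size
    if total < T:
        raise ValueError(f"cannot place {T} types in {total} cells with a floor of 1")
    remaining = total - T
    ideal = fractions * remaining
    counts = np.floor(ideal).astype(int)
    leftover = remaining - counts.sum()
    if leftover > 0:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:leftover]] += 1
    return counts + 1


def simulate_pseudobulk(
    sc: SyntheticSCData,
    n_samples: int = 20,
    cells_per_sample: int = 100,
    max_copies_per_type: int = 3,
    seed: int = 0,
) -> SimulatedDataset:
    """Mix labelled single cells into pseudo-bulk samples of known composition.

    Per sample: draw a composition from a Dirichlet whose parameter is the
    dataset's observed type proportions, convert it to integer cell counts
    (total ``cells_per_sample``, at least one cell per type), then sample
    cells with replacement drawing from at most ``max_copies_per_type``
    distinct cells per type.  The bulk value is the cumulative raw count,
    log-normalized (log1p of counts scaled to 10,000 per sample); the ground
    truth fraction is the realized cell-count proportion.
    """
    types = list(sc.cell_types)
    T = len(types)
    if cells_per_sample < T:
        raise ValueError("cells_per_sample must be >= number of types")
    if max_copies_per_type < 1:
        raise ValueError("max_copies_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    J = sc.counts.shape[0]
    type_idx = {t: np.flatnonzero(sc.labels == t) for t in types}
    for t, idx in type_idx.items():
        if idx.size == 0:
            raise ValueError(f"cell type {t!r} has no cells")
    observed = np.array([type_idx[t].size for t in types], dtype=float)
    concentration = observed / observed.sum()

    raw = np.zeros((J, n_samples))
    true_fractions = np.zeros((n_samples, T))
    true_x = np.zeros((n_samples, J, T))
    for i in range(n_samples):
        frac = rng.dirichlet(concentration)
        cell_counts = _apportion(frac, cells_per_sample)
        for t, n_t in enumerate(cell_counts):
            pool = type_idx[types[t]]
            n_distinct = min(max_copies_per_type, n_t, pool.size)
            chosen = rng.choice(pool, size=n_distinct, replace=False)
            draws = rng.choice(chosen, size=n_t, replace=True)
            contrib = sc.counts[:, draws].sum(axis=1)
            raw[:, i] += contrib
            true_x[i, :, t] = contrib / n_t          # mean count per cell
        true_fractions[i] = cell_counts / cells_per_sample

    lognorm = np.log1p(raw / raw.sum(axis=0, keepdims=True) * 1e4)
    bulk = BulkMatrix(
        lognorm,
        list(sc.gene_ids) or [f"gene{j}" for j in range(J)],
        [f"pseudobulk{i}" for i in range(n_samples)],
        "log",
    )
    return SimulatedDataset(
        bulk=bulk,
        true_fractions=true_fractions,
        true_x=true_x,
        true_mu=np.log(np.maximum(sc.type_means, 1e-12)),
        sigma=float("nan"),
        seed=seed,
        cell_types=types,
    )
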