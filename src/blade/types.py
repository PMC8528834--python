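"""Core data containers for the deconvolution model.

Dimensions follow a fixed convention: ``I`` samples, ``J`` genes, ``T`` cell
types.  Files store genes as rows and samples as columns; in memory the
variational tensors are sample-major, shaped ``(I, J, T)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BulkMatrix",
    "SignaturePrior",
    "VariationalState",
    "FitResult",
]


@dataclass
class BulkMatrix:
    """Bulk expression matrix, genes x samples.

    Parameters
    ----------
    values
        Non-negative expression values, shape ``(J, I)``. ``scale`` declares
        whether they are linear or log1p-normalized.
    gene_ids, sample_ids
        Row and column identifiers.
    scale
        ``"linear"`` or ``"log"``.
    """

    values: np.ndarray
    gene_ids: Sequence[str]
    sample_ids: Sequence[str]
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("bulk values must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"bulk shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("need at least one gene and one sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and np.any(self.values < 0):
            raise ValueError("negative entries in linear-scale bulk matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in bulk matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_linear(self) -> "BulkMatrix":
        """Return a linear-scale copy (expm1 of log-scale values)."""
        if self.scale == "linear":
            return self
        return BulkMatrix(np.expm1(self.values), self.gene_ids, self.sample_ids, "linear")

    def log_values(self) -> np.ndarray:
        """log of the linear values, zeros floored to half the smallest positive.

        Returns an ``(I, J)`` sample-major array ready for the likelihood.
        """
        lin = self.to_linear().values
        if np.any(lin <= 0):
            pos = lin[lin > 0]
            if pos.size == 0:
                raise ValueError("bulk matrix has no positive entries")
            floor = 0.5 * pos.min()
            warnings.warn(
                f"{int((lin <= 0).sum())} non-positive bulk entries floored to {floor:.3g} "
                "before log transform"
            )
            lin = np.where(lin <= 0, floor, lin)
        return np.log(lin).T.copy()


@dataclass
class SignaturePrior:
    """Per-(gene, type) normal-gamma prior plus shared scalar hyperparameters.

    ``mu0`` and ``sigma`` are the log-scale mean/SD signature; ``beta0`` is
    derived as ``alpha0 * sigma**2``.  ``gamma`` is the per-gene precision of
    the log-scale observation noise; ``dirichlet_alpha`` the flat pseudo-count
    of the fraction prior; ``s`` the noise scale factor used to derive gamma.
    """

    mu0: np.ndarray
    sigma: np.ndarray
    kappa0: float
    alpha0: float
    beta0: np.ndarray
    gamma: np.ndarray
    dirichlet_alpha: float
    s: float
    gene_ids: Sequence[str] = field(default_factory=list)
    cell_types: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not (self.mu0.shape == self.sigma.shape == self.beta0.shape):
            raise ValueError("mu0, sigma, beta0 must share a (genes x types) shape")
        if self.gamma.shape != (self.mu0.shape[0],):
            raise ValueError("gamma must be per-gene")
        for name, val in (("kappa0", self.kappa0), ("alpha0", self.alpha0),
                          ("dirichlet_alpha", self.dirichlet_alpha), ("s", self.s)):
            if not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if np.any(self.gamma <= 0):
            raise ValueError("gamma must be positive")
        if not np.allclose(self.beta0, self.alpha0 * self.sigma**2):
            raise ValueError("beta0 must equal alpha0 * sigma**2")

    @property
    def n_genes(self) -> int:
        return self.mu0.shape[0]

    @property
    def n_types(self) -> int:
        return self.mu0.shape[1]


@dataclass
class VariationalState:
    """Mean-field variational parameters.

    ``q(log x_ijt) = Normal(nu_ijt, omega_ijt)`` (``omega`` is a variance) and
    ``q(f_i) = Dirichlet(B_i)``.
    """

    nu: np.ndarray      # (I, J, T)
    omega: np.ndarray   # (I, J, T), variances > 0
    B: np.ndarray       # (I, T), Dirichlet parameters > 0

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.nu.ndim != 3 or self.nu.shape != self.omega.shape:
            raise ValueError("nu and omega must be (I, J, T) tensors of equal shape")
        if self.B.shape != (self.nu.shape[0], self.nu.shape[2]):
            raise ValueError("B must be (I, T)")
        for name, arr in (("nu", self.nu), ("omega", self.omega), ("B", self.B)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.omega <= 0):
            raise ValueError("omega must be strictly positive")
        if np.any(self.B <= 0):
            raise ValueError("B must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.nu.shape

    def copy(self) -> "VariationalState":
        return VariationalState(self.nu.copy(), self.omega.copy(), self.B.copy())


@dataclass
class FitResult:
    """Converged variational fit.

    ``fractions`` is the posterior-mean composition ``B / rowsum(B)``;
    ``objective_trace`` records the negative bound at each accepted iterate.
    """

    state: VariationalState
    objective_trace: np.ndarray
    fractions: np.ndarray
    converged: bool
    n_iter: int
    config: dict
    sample_ids: Sequence[str] = field(default_factory=list)
    gene_ids: Sequence[str] = field(default_factory=list)
    cell_types: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ValueError("fractions must be non-negative")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("fraction rows must sum to 1")
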