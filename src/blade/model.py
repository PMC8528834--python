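"""Model assembly, prior construction, and the variational fit.

The public entry points mirror a typical estimator workflow::

    prior  = build_prior(sig_mean, sig_sd, bulk, config)
    result = fit(bulk, prior, FitOptions(seed=0))
    frac   = result.fractions                    # samples x types
    xhat   = purify_high_resolution(result)      # samples x genes x types
    prof   = purify_group(result)                # genes x types
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import objective
from .types import BulkMatrix, FitResult, SignaturePrior, VariationalState

__all__ = [
    "FitOptions",
    "build_prior",
    "fit",
    "purify_high_resolution",
    "purify_group",
]

#: floor applied to the across-sample variance of log bulk expression when a
#: gene is constant across samples (its observation precision would diverge)
VARIANCE_FLOOR = 1e-2
#: floor applied to the signature SD before it becomes the prior sigma; a
#: zero SD would give beta0 = 0, an improper normal-gamma prior
SD_FLOOR = 0.05
#: floor for the initial variational variance
OMEGA_FLOOR = 1e-4


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit`."""

    max_iter: int = 10_000
    tol: float = 1e-5
    n_restarts: int = 1
    seed: int = 0
    jitter_sd: float = 0.1


def build_prior(
    signature_mean: np.ndarray,
    signature_sd: np.ndarray,
    bulk: BulkMatrix,
    config: dict,
    gene_ids=None,
    cell_types=None,
) -> SignaturePrior:
    """Turn a (mean, SD) log-scale signature into the normal-gamma prior.

    ``config`` supplies the shared scalars ``alpha`` (Dirichlet pseudo-count),
    ``alpha0``, ``kappa0`` and ``s``.  The prior location is the signature
    mean (``mu0 = mean``), the rate is ``beta0 = alpha0 * sd**2`` so that the
    prior variance of ``log x`` equals the signature variance, and the
    per-gene observation precision is ``gamma_j = 1 / (Var_j(log y) * s)``.

    Genes must be identically ordered between signature and bulk; pass
    ``gene_ids`` to have this checked against ``bulk.gene_ids``.
    """
    mean = np.asarray(signature_mean, dtype=float)
    sd = np.asarray(signature_sd, dtype=float)
    if mean.shape != sd.shape or mean.ndim != 2:
        raise ValueError("signature mean and sd must be 2-D arrays of equal shape")
    if mean.shape[0] != bulk.n_genes:
        raise ValueError(
            f"signature has {mean.shape[0]} genes but bulk has {bulk.n_genes}"
        )
    if gene_ids is not None and list(gene_ids) != list(bulk.gene_ids):
        raise KeyError("signature gene identifiers do not match bulk gene identifiers")
    if np.any(sd < 0):
        raise ValueError("signature SDs must be non-negative")
    for key in ("alpha", "alpha0", "kappa0", "s"):
        if key not in config:
            raise KeyError(f"config missing hyperparameter {key!r}")
        if not config[key] > 0:
            raise ValueError(f"hyperparameter {key!r} must be positive")

    if np.any(sd < SD_FLOOR):
        sd = np.maximum(sd, SD_FLOOR)

    logy = bulk.log_values()                      # (I, J)
    var = logy.var(axis=0, ddof=0)
    if np.any(var <= 0):
        warnings.warn(
            f"{int((var <= 0).sum())} gene(s) with zero across-sample bulk variance; "
            f"flooring variance at {VARIANCE_FLOOR}"
        )
        var = np.maximum(var, VARIANCE_FLOOR)
    gamma = 1.0 / (var * config["s"])

    return SignaturePrior(
        mu0=mean,
        sigma=sd,
        kappa0=float(config["kappa0"]),
        alpha0=float(config["alpha0"]),
        beta0=float(config["alpha0"]) * sd**2,
        gamma=gamma,
        dirichlet_alpha=float(config["alpha"]),
        s=float(config["s"]),
        gene_ids=list(gene_ids) if gene_ids is not None else list(bulk.gene_ids),
        cell_types=list(cell_types) if cell_types is not None else [],
    )


def _initial_state(prior: SignaturePrior, I: int) -> VariationalState:
    J, T = prior.mu0.shape
    nu = np.broadcast_to(prior.mu0[None], (I, J, T)).copy()
    omega = np.broadcast_to(
        np.maximum(prior.sigma**2, OMEGA_FLOOR)[None], (I, J, T)
    ).copy()
    B = np.full((I, T), prior.dirichlet_alpha, dtype=float)
    return VariationalState(nu, omega, B)


def _clean_bulk(bulk: BulkMatrix) -> BulkMatrix:
    """Linear-scale copy with zeros floored, so the log transform is stable."""
    lin = bulk.to_linear()
    vals = lin.values
    if np.any(vals <= 0):
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError("bulk matrix has no positive entries")
        floor = 0.5 * pos.min()
        warnings.warn(
            f"{int((vals <= 0).sum())} non-positive bulk entries floored to {floor:.3g}"
        )
        vals = np.where(vals <= 0, floor, vals)
        lin = BulkMatrix(vals, bulk.gene_ids, bulk.sample_ids, "linear")
    return lin


def fit(bulk: BulkMatrix, prior: SignaturePrior, opts: FitOptions | None = None) -> FitResult:
    """Fit the collapsed variational bound by L-BFGS-B, best of restarts.

    The bulk matrix is used on the linear scale internally (the log is taken
    inside the likelihood).  ``T = 1`` short-circuits: the single fraction is
    1 for every sample by construction.
    """
    opts = opts or FitOptions()
    if not np.all(np.isfinite(bulk.values)):
        raise ValueError("NaN or infinite values in bulk matrix")
    lin = _clean_bulk(bulk)
    I = lin.n_samples
    J, T = prior.mu0.shape
    if J < T:
        warnings.warn(
            f"fewer genes ({J}) than cell types ({T}); the model is underdetermined"
        )

    rng = np.random.default_rng(opts.seed)
    shape = (I, J, T)
    base = _initial_state(prior, I)

    best = None
    errors: list[str] = []
    for restart in range(max(1, opts.n_restarts)):
        state0 = base.copy()
        if restart > 0:
            state0.nu = state0.nu + rng.normal(0.0, opts.jitter_sd, size=shape)
        x0 = objective.pack(state0)
        trace: list[float] = []

        def value_and_grad(x):
            # line searches probe extreme points where the bound overflows;
            # a large penalty steers them back instead of aborting the fit
            st = objective.unpack(x, shape)
            try:
                return (
                    objective.neg_elbo(st, lin, prior),
                    objective.neg_elbo_grad(st, lin, prior),
                )
            except FloatingPointError:
                return 1e300, np.zeros_like(x)

        def callback(xk):
            trace.append(value_and_grad(xk)[0])

        res = minimize(
            value_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=callback,
            options={
                "maxfun": opts.max_iter,
                "maxiter": opts.max_iter,
                "gtol": opts.tol,
                "ftol": 1e-12,
            },
        )
        if not np.isfinite(res.fun):
            errors.append(str(res.message))
            continue
        if best is None or res.fun < best[0].fun:
            best = (res, trace)

    if best is None:
        raise RuntimeError(
            "optimizer failed on all restarts: " + "; ".join(errors)
        )
    res, trace = best
    state = objective.unpack(res.x, shape)
    if T == 1:
        fractions = np.ones((I, 1))
    else:
        fractions = state.B / state.B.sum(axis=1, keepdims=True)
    return FitResult(
        state=state,
        objective_trace=np.asarray([res.fun] if not trace else trace, dtype=float),
        fractions=fractions,
        converged=bool(res.success),
        n_iter=int(res.nit),
        config={
            "alpha": prior.dirichlet_alpha,
            "alpha0": prior.alpha0,
            "kappa0": prior.kappa0,
            "s": prior.s,
            "neg_elbo": float(res.fun),
            "message": str(res.message),
        },
        sample_ids=list(bulk.sample_ids),
        gene_ids=list(bulk.gene_ids),
        cell_types=list(prior.cell_types),
    )


def purify_high_resolution(result: FitResult) -> np.ndarray:
    """Posterior-mean purified expression per sample, gene and type.

    The posterior of ``x_ijt`` under q is log-normal with parameters
    ``(nu, omega)``, so the mean is ``exp(nu + omega / 2)`` — strictly
    positive, linear scale.
    """
    s = result.state
    return np.exp(s.nu + 0.5 * s.omega)


def purify_group(result: FitResult) -> np.ndarray:
    """Group-mode purification: per-type average profile across samples.

    Unweighted mean over the sample axis of the high-resolution posterior
    means; shape genes x types.
    """
    return purify_high_resolution(result).mean(axis=0)
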