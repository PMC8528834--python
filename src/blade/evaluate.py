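"""Scoring of fraction estimates and purified expression, plus an NNLS
baseline used in comparison studies.

Purification correlations are computed on the log scale: the generative model
is log-normal and linear-scale correlation is dominated by the handful of
most-expressed genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr, spearmanr

__all__ = ["ScoreReport", "score_fractions", "score_purification", "nnls_baseline"]


@dataclass
class ScoreReport:
    """Per-type and pooled accuracy metrics."""

    per_type: pd.DataFrame      # columns: cell_type, pearson, spearman, rmse
    overall: dict
    mode: str


def _safe_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(pearson, spearman), NaN when either vector is constant."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant vector; correlation undefined, reported as NaN")
        return float("nan"), float("nan")
    return float(pearsonr(a, b)[0]), float(spearmanr(a, b)[0])


def score_fractions(truth: np.ndarray, estimate: np.ndarray, cell_types=None) -> ScoreReport:
    """Score estimated fractions against truth, per type across samples.

    Both arrays are samples x types with identical type ordering.  Pooled
    metrics flatten all (sample, type) pairs.
    """
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {estimate.shape}")
    T = truth.shape[1]
    cell_types = list(cell_types) if cell_types is not None else [f"type{t}" for t in range(T)]
    rows = []
    for t in range(T):
        pe, sp = _safe_corr(truth[:, t], estimate[:, t])
        rows.append({
            "cell_type": cell_types[t],
            "pearson": pe,
            "spearman": sp,
            "rmse": float(np.sqrt(np.mean((truth[:, t] - estimate[:, t]) ** 2))),
        })
    pe, sp = _safe_corr(truth.ravel(), estimate.ravel())
    overall = {
        "pearson": pe,
        "spearman": sp,
        "rmse": float(np.sqrt(np.mean((truth - estimate) ** 2))),
    }
    return ScoreReport(pd.DataFrame(rows), overall, "fractions")


def score_purification(
    truth_x: np.ndarray, estimate_x: np.ndarray, mode: str = "group", cell_types=None
) -> ScoreReport:
    """Score purified expression on the log scale.

    ``mode="group"``: genes x types matrices, one correlation per type across
    genes.  ``mode="highres"``: samples x genes x types tensors, one
    correlation per (type, sample) across genes, summarized per type; the
    per-pair table is attached as ``overall["per_pair"]`` (T x I rows).
    Inputs must be on a common scale; mixing linear- and log-scale arrays is
    flagged when exactly one of them contains negative values.
    """
    truth_x = np.asarray(truth_x, dtype=float)
    estimate_x = np.asarray(estimate_x, dtype=float)
    if truth_x.shape != estimate_x.shape:
        raise ValueError(f"shape mismatch: {truth_x.shape} vs {estimate_x.shape}")
    if (truth_x.min() < 0) != (estimate_x.min() < 0):
        warnings.warn(
            "possible scale mismatch: exactly one of truth/estimate contains "
            "negative values (log vs linear scale?)"
        )

    def to_log(a):
        return np.log(np.maximum(a, 1e-12)) if a.min() >= 0 else a

    lt, le = to_log(truth_x), to_log(estimate_x)
    if mode == "group":
        if lt.ndim != 2:
            raise ValueError("group mode expects genes x types matrices")
        T = lt.shape[1]
        cell_types = list(cell_types) if cell_types is not None else [f"type{t}" for t in range(T)]
        rows = []
        for t in range(T):
            pe, sp = _safe_corr(lt[:, t], le[:, t])
            rows.append({
                "cell_type": cell_types[t], "pearson": pe, "spearman": sp,
                "rmse": float(np.sqrt(np.mean((lt[:, t] - le[:, t]) ** 2))),
            })
        pe, sp = _safe_corr(lt.ravel(), le.ravel())
        overall = {"pearson": pe, "spearman": sp,
                   "rmse": float(np.sqrt(np.mean((lt - le) ** 2)))}
        return ScoreReport(pd.DataFrame(rows), overall, "group_purification")
    if mode == "highres":
        if lt.ndim != 3:
            raise ValueError("highres mode expects samples x genes x types tensors")
        I, _, T = lt.shape
        cell_types = list(cell_types) if cell_types is not None else [f"type{t}" for t in range(T)]
        pairs = []
        for t in range(T):
            for i in range(I):
                pe, sp = _safe_corr(lt[i, :, t], le[i, :, t])
                pairs.append({
                    "cell_type": cell_types[t], "sample": i, "pearson": pe,
                    "spearman": sp,
                    "rmse": float(np.sqrt(np.mean((lt[i, :, t] - le[i, :, t]) ** 2))),
                })
        per_pair = pd.DataFrame(pairs)
        per_type = (
            per_pair.groupby("cell_type", sort=False)[["pearson", "spearman", "rmse"]]
            .mean()
            .reset_index()
        )
        overall = {
            "pearson": float(per_pair["pearson"].mean()),
            "spearman": float(per_pair["spearman"].mean()),
            "rmse": float(per_pair["rmse"].mean()),
            "per_pair": per_pair,
        }
        return ScoreReport(per_type, overall, "highres_purification")
    raise ValueError(f"unknown mode {mode!r}")


def nnls_baseline(bulk, signature_mean: np.ndarray) -> np.ndarray:
    """Non-negative least-squares deconvolution, renormalized to the simplex.

    ``signature_mean`` is the log-scale gene x type signature; it is
    exponentiated so the regression runs on the linear scale, matching how
    average profiles are fed to linear deconvolution methods.  A
    rank-deficient signature falls back to a clipped pseudo-inverse solution
    with a warning.
    """
    from .types import BulkMatrix

    if isinstance(bulk, BulkMatrix):
        values = bulk.to_linear().values
    else:
        values = np.asarray(bulk, dtype=float)
    S = np.exp(np.asarray(signature_mean, dtype=float))
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn("rank-deficient signature; using pseudo-inverse with clipping")
        coef = np.clip(np.linalg.pinv(S) @ values, 0.0, None).T
    else:
        coef = np.array([nnls(S, values[:, i])[0] for i in range(values.shape[1])])
    total = coef.sum(axis=1, keepdims=True)
    flat = np.flatnonzero(total.ravel() == 0)
    if flat.size:
        warnings.warn(f"all-zero NNLS solution for sample(s) {flat.tolist()}; uniform fallback")
        coef[flat] = 1.0
        total = coef.sum(axis=1, keepdims=True)
    return coef / total
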