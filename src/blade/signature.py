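"""Signature construction from labelled single-cell expression.

The pipeline is: log-normalize counts per cell, run a one-vs-rest two-sided
Wilcoxon rank-sum test per cell type, select up to ``top_n`` genes per type
under a Benjamini-Hochberg FDR cutoff, and summarize each type's cells by the
per-gene mean and SD of log-normalized expression over the combined panel.
These two matrices are exactly the ``(signature_mean, signature_sd)`` input
of :func:`blade.model.build_prior`.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_normalize",
    "deg_one_vs_rest",
    "build_signature",
    "unique_degs",
]


def log_normalize(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Per-cell log normalization: ``log1p(count / column_sum * scale)``.

    ``counts`` is genes x cells with non-negative integer entries; a cell
    with zero total counts cannot be normalized and raises.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not scale > 0:
        raise ValueError("scale must be positive")
    colsum = counts.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"cell column(s) {zero.tolist()} have zero total counts")
    return np.log1p(counts / colsum[None, :] * scale)


def deg_one_vs_rest(
    expr: np.ndarray,
    labels: Sequence[str],
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest differential expression per cell type.

    For every (gene, type) pair: two-sided Wilcoxon rank-sum (Mann-Whitney U)
    statistic and p-value contrasting the type's cells against all others,
    with Benjamini-Hochberg FDR computed within each type's contrast, and the
    mean log-expression difference as the log fold change.

    Types with fewer than two cells are skipped with a warning.  Genes that
    are constant across all cells get p = 1 (the test carries no information
    under pure ties).
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    J, n = expr.shape
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per cell")
    types = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    if len(types) < 2:
        raise ValueError("need at least two cell types for a one-vs-rest contrast")
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene{j}" for j in range(J)]

    frames = []
    constant = np.ptp(expr, axis=1) == 0
    for t in types:
        mask = labels == t
        if mask.sum() < 2:
            warnings.warn(f"cell type {t!r} has fewer than 2 cells; skipped")
            continue
        a, b = expr[:, mask], expr[:, ~mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = mannwhitneyu(a, b, axis=1, alternative="two-sided")
        p = np.where(np.isnan(p) | constant, 1.0, p)
        fdr = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene_ids,
                    "cell_type": t,
                    "statistic": stat,
                    "p_value": p,
                    "fdr": fdr,
                    "log_fold_change": a.mean(axis=1) - b.mean(axis=1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _select_per_type(table: pd.DataFrame, fdr_cutoff: float, top_n: int) -> dict[str, list[str]]:
    """Per-type gene selection: FDR < cutoff, ranked by (FDR asc, |stat| desc)."""
    selected: dict[str, list[str]] = {}
    for t, sub in table.groupby("cell_type", sort=False):
        hits = sub[sub["fdr"] < fdr_cutoff].copy()
        hits["abs_stat"] = hits["statistic"].abs()
        hits = hits.sort_values(["fdr", "abs_stat"], ascending=[True, False], kind="stable")
        selected[t] = hits["gene"].head(top_n).tolist()
    return selected


def build_signature(
    expr: np.ndarray,
    labels: Sequence[str],
    top_n: int = 200,
    fdr_cutoff: float = 0.2,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Build the (mean, SD) signature over a DEG-selected gene panel.

    Returns ``(mean, sd, panel)``: two genes x types DataFrames of per-type
    mean and SD of log-normalized expression restricted to the panel — the
    union over types of up to ``top_n`` genes passing ``fdr_cutoff`` — plus
    the panel itself in input gene order.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene{j}" for j in range(expr.shape[0])]
    table = deg_one_vs_rest(expr, labels, gene_ids)
    selected = _select_per_type(table, fdr_cutoff, top_n)
    union = set().union(*selected.values()) if selected else set()
    if not union:
        raise ValueError(
            f"no gene passed FDR < {fdr_cutoff}; loosen the cutoff or check the labels"
        )
    panel = [g for g in gene_ids if g in union]
    idx = [gene_ids.index(g) for g in panel]
    types = list(dict.fromkeys(table["cell_type"].tolist()))

    mean = np.empty((len(panel), len(types)))
    sd = np.empty_like(mean)
    for k, t in enumerate(types):
        cells = expr[np.ix_(idx, np.flatnonzero(labels == t))]
        mean[:, k] = cells.mean(axis=1)
        sd[:, k] = cells.std(axis=1, ddof=1)
    mean_df = pd.DataFrame(mean, index=panel, columns=types)
    sd_df = pd.DataFrame(sd, index=panel, columns=types)
    return mean_df, sd_df, panel


def unique_degs(
    table: pd.DataFrame, fdr_cutoff: float = 0.2, top_n: int = 200
) -> pd.Series:
    """Count, per type, the genes significant for exactly that one type.

    A gene counts for a type only if it enters that type's selection (FDR
    cutoff plus top-N ranking) and no other type's.
    """
    selected = _select_per_type(table, fdr_cutoff, top_n)
    types = list(selected)
    counts = {}
    for t in types:
        others = set().union(*(selected[u] for u in types if u != t)) if len(types) > 1 else set()
        counts[t] = sum(1 for g in selected[t] if g not in others)
    return pd.Series(counts, name="unique_degs")
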