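"""Signature construction: normalization, DEG testing, panel selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from blade.signature import build_signature, deg_one_vs_rest, log_normalize, unique_degs
from blade.simulate import generate_synthetic_sc


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self):
        counts = np.array([[0, 5], [10, 5]])
        out = log_normalize(counts, scale=100)
        assert out[0, 0] == 0.0

    def test_single_gene_cell(self):
        """A cell expressing one gene with count c normalizes to log1p(scale)."""
        counts = np.array([[7], [0]])
        out = log_normalize(counts, scale=1e4)
        assert out[0, 0] == pytest.approx(np.log1p(1e4))

    def test_normalization_identity(self):
        """expm1 of the output sums to `scale` per cell."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(30, 8))
        counts[0] += 1  # no all-zero cells
        out = log_normalize(counts, scale=1e4)
        np.testing.assert_allclose(np.expm1(out).sum(axis=0), 1e4, rtol=1e-9)

    def test_all_zero_cell_raises_with_name(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            log_normalize(counts)


def exact_ranksum_pvalue(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    observed = ranks[:n].sum()
    stats = [
        sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n)
    ]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


class TestDegOneVsRest:
    def test_exact_small_sample_pvalue(self):
        """(1,2,3 | 10,11,12): exact two-sided rank-sum p = 0.1 = 2/C(6,3)."""
        expr = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        table = deg_one_vs_rest(expr, labels)
        p = table.loc[table.cell_type == "a", "p_value"].iloc[0]
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(
            exact_ranksum_pvalue(expr[0, :3], expr[0, 3:]), abs=1e-12
        )

    def test_constant_gene_p_is_one(self):
        expr = np.vstack([np.full(8, 3.0), np.arange(8, dtype=float)])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        table = deg_one_vs_rest(expr, labels)
        assert (table.loc[table.gene == "gene0", "p_value"] == 1.0).all()

    def test_planted_degs_rank_above_background(self):
        """Planted markers dominate the FDR ranking of their own type."""
        sc = generate_synthetic_sc(J=300, T=3, cells_per_type=100,
                                   n_deg_per_type=10, effect_size=2.0, seed=4)
        expr = log_normalize(sc.counts)
        table = deg_one_vs_rest(expr, sc.labels, sc.gene_ids)
        hits = 0
        for t, genes in sc.planted_degs.items():
            sub = table[table.cell_type == t].sort_values("fdr", kind="stable")
            top = set(sub.head(len(genes))["gene"])
            hits += len(top & set(genes))
        assert hits / 30 >= 0.95

    def test_small_type_skipped_with_warning(self):
        expr = np.random.default_rng(0).normal(size=(5, 7))
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"])
        with pytest.warns(UserWarning, match="'c'"):
            table = deg_one_vs_rest(expr, labels)
        assert set(table.cell_type) == {"a", "b"}

    def test_fdr_monotone_in_sorted_pvalues(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(40, 20))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        table = deg_one_vs_rest(expr, labels)
        for _, sub in table.groupby("cell_type"):
            s = sub.sort_values("p_value")
            assert s["fdr"].is_monotonic_increasing
            assert s["fdr"].between(0, 1).all()


@pytest.fixture(scope="module")
def sc():
    return generate_synthetic_sc(J=300, T=3, cells_per_type=60,
                                 n_deg_per_type=10, effect_size=2.0, seed=7)


class TestBuildSignature:

    def test_mean_sd_on_log_scale(self, sc):
        expr = log_normalize(sc.counts)
        mean, sd, panel = build_signature(expr, sc.labels, top_n=20, fdr_cutoff=0.2,
                                          gene_ids=sc.gene_ids)
        g = panel[0]
        j = sc.gene_ids.index(g)
        cells = expr[j, sc.labels == sc.cell_types[0]]
        assert mean.loc[g, sc.cell_types[0]] == pytest.approx(cells.mean())
        assert sd.loc[g, sc.cell_types[0]] == pytest.approx(cells.std(ddof=1))

    def test_constant_gene_within_type_sd_zero(self):
        expr = np.array([[5.0] * 3 + [1.0, 2.0, 3.0], [0.0, 2.0, 4.0, 9.0, 8.0, 7.0]])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        mean, sd, panel = build_signature(expr, labels, top_n=5, fdr_cutoff=1.0,
                                          gene_ids=["g0", "g1"])
        if "g0" in panel:
            assert mean.loc["g0", "a"] == 5.0 and sd.loc["g0", "a"] == 0.0

    def test_panel_invariant_to_cell_order(self, sc):
        expr = log_normalize(sc.counts)
        _, _, panel = build_signature(expr, sc.labels, top_n=15, fdr_cutoff=0.2,
                                      gene_ids=sc.gene_ids)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.shape[1])
        _, _, panel2 = build_signature(expr[:, perm], sc.labels[perm], top_n=15,
                                       fdr_cutoff=0.2, gene_ids=sc.gene_ids)
        assert panel == panel2

    def test_empty_panel_raises(self):
        rng = np.random.default_rng(3)
        expr = rng.normal(size=(20, 12))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.raises(ValueError, match="[Ll]oosen"):
            build_signature(expr, labels, top_n=5, fdr_cutoff=1e-12)

    def test_top_n_union_bound(self, sc):
        expr = log_normalize(sc.counts)
        _, _, panel = build_signature(expr, sc.labels, top_n=1, fdr_cutoff=0.2,
                                      gene_ids=sc.gene_ids)
        assert len(panel) <= 3


class TestUniqueDegs:
    def test_shared_gene_counts_zero(self):
        table = pd.DataFrame({
            "gene": ["g"] * 3,
            "cell_type": ["a", "b", "c"],
            "statistic": [30.0, 28.0, 27.0],
            "p_value": [1e-6] * 3,
            "fdr": [1e-5] * 3,
            "log_fold_change": [1.0, 0.9, 0.8],
        })
        counts = unique_degs(table, fdr_cutoff=0.2, top_n=10)
        assert (counts == 0).all()

    def test_disjoint_planted_sets_counted_exactly(self):
        """With top_n = planted block size, unique counts equal block sizes."""
        sc = generate_synthetic_sc(J=300, T=3, cells_per_type=100,
                                   n_deg_per_type=10, effect_size=2.0, seed=5)
        expr = log_normalize(sc.counts)
        table = deg_one_vs_rest(expr, sc.labels, sc.gene_ids)
        counts = unique_degs(table, fdr_cutoff=0.2, top_n=10)
        assert counts.sum() <= 30
        assert (counts >= 8).all()  # allow a stray rank swap per type

    def test_sum_bounded_by_panel(self):
        sc = generate_synthetic_sc(J=200, T=3, cells_per_type=40,
                                   n_deg_per_type=8, effect_size=2.0, seed=9)
        expr = log_normalize(sc.counts)
        table = deg_one_vs_rest(expr, sc.labels, sc.gene_ids)
        _, _, panel = build_signature(expr, sc.labels, top_n=20, fdr_cutoff=0.2,
                                      gene_ids=sc.gene_ids)
        counts = unique_degs(table, fdr_cutoff=0.2, top_n=20)
        assert counts.sum() <= len(panel)


def test_signature_prior_fit_roundtrip():
    """Full path: synthetic cells -> signature -> prior -> deconvolution.

    Pseudo-bulk mixtures of the same cells must be deconvolved at r >= 0.8
    using only the estimated signature (no ground-truth parameters).
    """
    from scipy.stats import pearsonr

    from blade import FitOptions, build_prior, fit
    from blade.simulate import simulate_pseudobulk
    from blade.types import BulkMatrix

    gen = generate_synthetic_sc(J=400, T=4, cells_per_type=200, n_deg_per_type=15,
                                effect_size=2.0, seed=2)
    expr = log_normalize(gen.counts)
    mean, sd, panel = build_signature(expr, gen.labels, top_n=200, fdr_cutoff=0.2,
                                      gene_ids=gen.gene_ids)
    ds = simulate_pseudobulk(gen, n_samples=15, cells_per_sample=100, seed=3)
    keep = [ds.bulk.gene_ids.index(g) for g in panel]
    bulk = BulkMatrix(ds.bulk.values[keep], panel, ds.bulk.sample_ids, ds.bulk.scale)
    prior = build_prior(mean.to_numpy(), sd.to_numpy(), bulk,
                        {"alpha": 1.0, "alpha0": 1.0, "kappa0": 1.0, "s": 1.0})
    res = fit(bulk, prior, FitOptions(seed=0))
    r = pearsonr(ds.true_fractions.ravel(), res.fractions.ravel())[0]
    assert r >= 0.8, f"round-trip fraction r = {r:.3f}"
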