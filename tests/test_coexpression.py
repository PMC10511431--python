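"""Gene filtering and query-gene correlation profiling."""

import numpy as np
import pandas as pd
import pytest

from pancontext.coexpression import (
    counts_vs_level,
    filter_genes,
    overlap_with_reference,
    profile_contexts,
    significant_genes,
    spearman_profile,
    union_correlated_genes,
)
from pancontext.datamodel import ExpressionMatrix


def _matrix(data, samples=None, shift=0.0):
    """Gene-by-sample matrix; ``shift`` lifts centered draws onto the
    non-negative log-expression scale without touching ranks."""
    df = pd.DataFrame(data).T + shift
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


class TestFilterGenes:
    def test_constant_gene_dropped_and_rule_boundary(self):
        m = _matrix(
            {
                "const": [1.0, 1.0, 1.0, 1.0],
                "good": [0.3, 0.5, 0.8, 1.1],  # mean .675 > .5, sd ~.35 > .2
                "low": [0.1, 0.2, 0.1, 0.2],
            }
        )
        groups = pd.Series(["A", "A", "B", "B"], index=m.sample_ids)
        kept = filter_genes(m, groups)
        assert "const" not in kept and "low" not in kept
        assert "good" in kept

    def test_kept_if_passing_in_one_type_only(self):
        m = _matrix(
            {"g": [0.35, 0.45, 0.85, 0.35]},  # B group: mean 0.6, sd ~0.35
        )
        groups = pd.Series(["A", "A", "B", "B"], index=m.sample_ids)
        assert filter_genes(m, groups) == ["g"]
        only_a = pd.Series(["A", "A"], index=["s0", "s1"])
        assert filter_genes(m, only_a) == []

    def test_query_force_retained_and_empty_grouping(self):
        m = _matrix({"q": [1.0, 1.0, 1.0, 1.0]})
        groups = pd.Series(["A"] * 4, index=m.sample_ids)
        assert filter_genes(m, groups, query_gene="q") == ["q"]
        with pytest.raises(ValueError, match="empty"):
            filter_genes(m, pd.Series(dtype=object))


class TestSpearmanProfile:
    def test_query_excluded_and_values(self, rng):
        n = 30
        q = rng.normal(size=n)
        m = _matrix({"q": q, "twin": q.copy(), "noise": rng.normal(size=n)}, shift=10.0)
        prof = spearman_profile(m, "q", m.sample_ids, "CT")
        assert "q" not in prof.table.index
        assert prof.table.loc["twin", "rho"] == pytest.approx(1.0)
        assert prof.table.loc["twin", "q"] < 1e-10

    def test_absent_query_raises(self, rng):
        m = _matrix({"a": rng.normal(size=5)}, shift=10.0)
        with pytest.raises(KeyError):
            spearman_profile(m, "nope", m.sample_ids)

    def test_zero_variance_gene_outside_bh_family(self, rng):
        n = 20
        m = _matrix({"q": rng.normal(size=n), "flat": np.ones(n), "g": rng.normal(size=n)}, shift=10.0)
        prof = spearman_profile(m, "q", m.sample_ids)
        assert np.isnan(prof.table.loc["flat", "rho"])
        assert np.isnan(prof.table.loc["flat", "q"])
        assert np.isfinite(prof.table.loc["g", "q"])


class TestSignificanceScreens:
    def test_threshold_screen_and_union(self, small_spec, small_cohort):
        expr, ann = small_cohort
        profiles = profile_contexts(expr, ann, small_spec.query_gene)
        assert len(profiles) == 3
        mods = small_spec.module_gene_ids()
        union, rho_matrix = union_correlated_genes(profiles, threshold=0.6)
        # rho* = 0.7 module members dominate the positive screen
        pos_hits = set(union) & set(mods["POSMOD"])
        assert len(pos_hits) >= 0.9 * len(mods["POSMOD"])
        assert rho_matrix.shape[1] == 3
        assert set(rho_matrix.index) == set(union)

    def test_empty_when_below_threshold(self, rng):
        n = 50
        m = _matrix({"q": rng.normal(size=n), "g": rng.normal(size=n)}, shift=10.0)
        prof = spearman_profile(m, "q", m.sample_ids)
        pos, neg = significant_genes(prof, threshold=0.99)
        assert pos == [] and neg == []

    def test_union_idempotent_on_identical_contexts(self, rng):
        n = 40
        q = rng.normal(size=n)
        g = q + rng.normal(0, 0.1, n)
        m = _matrix({"q": q, "g": g}, shift=10.0)
        p1 = spearman_profile(m, "q", m.sample_ids, "A")
        p2 = spearman_profile(m, "q", m.sample_ids, "B")
        union, _ = union_correlated_genes([p1, p2], 0.6)
        assert union == ["g"]


class TestCountsVsLevel:
    def test_monotone_counts_give_rho_one(self):
        counts = pd.DataFrame(
            {"total": range(10), "positive": range(10), "negative": [0] * 10},
            index=[f"T{i}" for i in range(10)],
        )
        level = pd.Series(np.linspace(0, 1, 10), index=counts.index)
        out = counts_vs_level(counts, level)
        assert out["total"] == pytest.approx(1.0)
        assert np.isnan(out["negative"])  # zero variance -> reported missing

    def test_too_few_types(self):
        counts = pd.DataFrame({"total": [1, 2], "positive": [1, 2], "negative": [0, 0]},
                              index=["A", "B"])
        with pytest.raises(ValueError):
            counts_vs_level(counts, pd.Series([0.1, 0.2], index=["A", "B"]))

    def test_decoupled_counts_rarely_correlate(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            idx = [f"T{i}" for i in range(20)]
            counts = pd.DataFrame(
                {"total": rng.integers(0, 100, 20),
                 "positive": rng.integers(0, 50, 20),
                 "negative": rng.integers(0, 50, 20)},
                index=idx,
            )
            level = pd.Series(rng.normal(size=20), index=idx)
            if abs(counts_vs_level(counts, level)["total"]) < 0.5:
                hits += 1
        assert hits >= 0.95 * 40 - 2


class TestOverlap:
    def test_disjoint_identical_and_oracle(self, rng):
        assert overlap_with_reference(["a", "b"], ["c"]) == ([], 0)
        genes = [f"g{i}" for i in range(100)]
        assert overlap_with_reference(genes, genes)[1] == 100
        sub = list(rng.choice(genes, 30, replace=False))
        ref = list(rng.choice(genes, 40, replace=False))
        got, n = overlap_with_reference(sub, ref)
        assert set(got) == set(sub) & set(ref) and n == len(set(sub) & set(ref))
        # order-stable: follows the query list order
        assert got == [g for g in sub if g in set(ref)]
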