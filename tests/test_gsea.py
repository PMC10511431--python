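"""Enrichment-score engine against brute-force enumeration."""

import numpy as np
import pandas as pd
import pytest

from pancontext.datamodel import GeneSetCollection
from pancontext.gsea import (
    assemble_collection,
    enrichment_score,
    normalized_enrichment,
    significant_genesets,
)


def brute_force_es(scores, hit_flags, exponent):
    """Direct enumeration of the weighted KS running sum."""
    n = len(scores)
    nh = sum(hit_flags)
    denom_hit = sum(abs(s) ** exponent for s, h in zip(scores, hit_flags) if h)
    run, best = 0.0, 0.0
    for s, h in zip(scores, hit_flags):
        if h:
            run += abs(s) ** exponent / denom_hit
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def _ranked(scores):
    return pd.Series(scores, index=[f"g{i}" for i in range(len(scores))])


class TestEnrichmentScore:
    def test_single_gene_at_top_is_one(self):
        ranked = _ranked(np.arange(10, 0, -1, dtype=float))
        es, _ = enrichment_score(ranked, {"g0"}, exponent=0)
        assert es == pytest.approx(1.0)

    def test_single_gene_at_bottom_matches_enumeration(self):
        ranked = _ranked(np.arange(10, 0, -1, dtype=float))
        es, _ = enrichment_score(ranked, {"g9"}, exponent=0)
        flags = [False] * 9 + [True]
        assert es == pytest.approx(brute_force_es(ranked.to_numpy(), flags, 0))
        assert es == pytest.approx(-1.0)  # nine -1/9 misses precede the hit

    def test_five_gene_hand_case(self):
        # scores (5,4,3,2,1), set = top two, exponent 1:
        # steps +5/9, +4/9, -1/3, -1/3, -1/3 -> extremum at position 2 = 1.0
        ranked = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, rs = enrichment_score(ranked, {"g0", "g1"}, exponent=1)
        np.testing.assert_allclose(
            rs, [5 / 9, 1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12
        )
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("exponent", [0, 1])
    def test_matches_brute_force_on_random_short_lists(self, seed, exponent):
        rng = np.random.default_rng(seed)
        n = 10
        scores = np.sort(rng.normal(size=n))[::-1]
        k = rng.integers(1, n - 1)
        members = rng.choice(n, size=k, replace=False)
        ranked = _ranked(scores)
        genes = {f"g{i}" for i in members}
        es, _ = enrichment_score(ranked, genes, exponent=exponent)
        flags = [i in set(members) for i in range(n)]
        assert es == pytest.approx(brute_force_es(scores, flags, exponent), abs=1e-12)

    def test_reversal_negates_es_at_exponent_zero(self, rng):
        scores = np.sort(rng.normal(size=20))[::-1]
        ranked = _ranked(scores)
        genes = {"g2", "g5", "g11"}
        es_fwd, _ = enrichment_score(ranked, genes, exponent=0)
        rev = pd.Series(scores[::-1], index=ranked.index[::-1])
        es_rev, _ = enrichment_score(rev, genes, exponent=0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_degenerate_sets_raise(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, {"zz"})
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, {"g0", "g1", "g2"})


class TestNormalizedEnrichment:
    def test_same_seed_reproducible_and_duplicate_set_identical(self, rng):
        scores = pd.Series(
            np.sort(rng.normal(size=300))[::-1], index=[f"g{i}" for i in range(300)]
        )
        members = list(rng.choice(scores.index, 30, replace=False))
        coll = GeneSetCollection()
        coll.add("A", members)
        coll.add("B", members)  # same set, different name
        r1 = normalized_enrichment(scores, coll, n_perm=200, seed=5)
        r2 = normalized_enrichment(scores, coll, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        assert r1.loc["A", "es"] == r1.loc["B", "es"]
        # same size -> shared permutation null at fixed seed -> identical NES
        assert r1.loc["A", "nes"] == r1.loc["B", "nes"]

    def test_sign_consistency_and_q_range(self, rng):
        scores = pd.Series(
            np.sort(rng.normal(size=500))[::-1], index=[f"g{i}" for i in range(500)]
        )
        coll = GeneSetCollection()
        coll.add("TOP", list(scores.index[:40]))
        coll.add("BOTTOM", list(scores.index[-40:]))
        res = normalized_enrichment(scores, coll, n_perm=200, seed=1)
        assert res.loc["TOP", "es"] > 0 and res.loc["TOP", "nes"] > 0
        assert res.loc["BOTTOM", "es"] < 0 and res.loc["BOTTOM", "nes"] < 0
        assert ((res["q"] >= 0) & (res["q"] <= 1)).all()

    def test_min_permutations_enforced(self, rng):
        scores = _ranked(np.arange(20, 0, -1, dtype=float))
        coll = GeneSetCollection()
        coll.add("S", ["g1", "g2"])
        with pytest.raises(ValueError, match="n_perm"):
            normalized_enrichment(scores, coll, n_perm=10)


class TestReportingRule:
    def _result(self, nes, q, context="CT1"):
        return pd.DataFrame(
            {"es": [nes / 2], "nes": [nes], "p": [0.01], "q": [q],
             "n_hits": [10], "n_perm": [200], "context": [context]},
            index=pd.Index(["S"], name="geneset"),
        )

    def test_passing_in_one_context_reports_all_contexts(self):
        res = {
            "CT1": self._result(2.4, 0.0005, "CT1"),
            "CT2": self._result(0.5, 0.9, "CT2"),
        }
        out = significant_genesets(res)
        assert set(out["context"]) == {"CT1", "CT2"}

    def test_failing_everywhere_not_reported(self):
        res = {"CT1": self._result(2.4, 0.002), "CT2": self._result(2.2, 0.0001)}
        assert significant_genesets(res).empty


class TestAssemble:
    def test_merge_and_collision(self):
        a, b = GeneSetCollection(), GeneSetCollection()
        a.add("S1", {"x"}, "hallmark")
        a.add("S2", {"y"}, "hallmark")
        b.add("S3", {"z"}, "custom")
        b.add("S4", {"w"}, "custom")
        merged = assemble_collection(a, b)
        assert len(merged) == 4
        assert merged.provenance["S3"] == "custom"
        c = GeneSetCollection()
        c.add("S1", {"q"})
        with pytest.raises(ValueError, match="S1"):
            assemble_collection(a, c)
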