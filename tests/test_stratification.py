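"""TP53-stratified comparisons and the delta framework."""

import numpy as np
import pandas as pd
import pytest

from pancontext.coexpression import CorrelationProfile, profile_contexts, spearman_profile
from pancontext.datamodel import ExpressionMatrix
from pancontext.stratification import (
    compare_expression_by_status,
    delta_correlation,
    delta_nes,
    delta_union,
    eligible_contexts,
)


def _ann(rows):
    base = {"os_time": 100.0, "os_event": False, "size_stage": np.nan,
            "node_stage": np.nan, "met_stage": np.nan}
    return pd.DataFrame([dict(base, **r) for r in rows])


def _expr_from(q_vals, sample_ids):
    df = pd.DataFrame({"QG": q_vals}, index=sample_ids).T
    return ExpressionMatrix(df)


class TestCompareByStatus:
    def test_identical_groups_t_zero_p_one(self):
        samples = [f"s{i}" for i in range(6)]
        expr = _expr_from([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], samples)
        ann = _ann(
            [{"sample_id": s, "cancer_type": "A",
              "tp53_status": "WT" if i < 3 else "MUT",
              "tp53_class": "WT" if i < 3 else "InframeMissense"}
             for i, s in enumerate(samples)]
        )
        out = compare_expression_by_status(expr, ann, "QG")
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        samples = [f"s{i}" for i in range(6)]
        expr = _expr_from([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], samples)
        ann = _ann(
            [{"sample_id": s, "cancer_type": "A",
              "tp53_status": "WT" if i < 3 else "MUT",
              "tp53_class": "WT" if i < 3 else "InframeMissense"}
             for i, s in enumerate(samples)]
        )
        out = compare_expression_by_status(expr, ann, "QG")
        # means 2 vs 5, pooled var = 1, se = sqrt(2/3), t = -3/se
        t_hand = -3.0 / np.sqrt(2.0 / 3.0)
        assert out.loc[0, "t"] == pytest.approx(t_hand, abs=1e-12)
        assert out.loc[0, "n_a"] == out.loc[0, "n_b"] == 3

    def test_small_group_skipped(self):
        samples = ["a", "b", "c"]
        expr = _expr_from([1.0, 2.0, 3.0], samples)
        ann = _ann(
            [{"sample_id": "a", "cancer_type": "A", "tp53_status": "WT", "tp53_class": "WT"},
             {"sample_id": "b", "cancer_type": "A", "tp53_status": "WT", "tp53_class": "WT"},
             {"sample_id": "c", "cancer_type": "A", "tp53_status": "MUT",
              "tp53_class": "InframeMissense"}]
        )
        assert compare_expression_by_status(expr, ann, "QG").empty

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        detections = 0
        for rep in range(20):
            n = 200
            wt = rng.normal(0.0, 1.0, n)
            mut = rng.normal(1.0, 1.0, n)  # 1 SD shift
            samples = [f"s{i}" for i in range(2 * n)]
            expr = _expr_from(np.abs(np.concatenate([wt, mut])), samples)
            ann = _ann(
                [{"sample_id": s, "cancer_type": "A",
                  "tp53_status": "WT" if i < n else "MUT",
                  "tp53_class": "WT" if i < n else "InframeMissense"}
                 for i, s in enumerate(samples)]
            )
            out = compare_expression_by_status(expr, ann, "QG")
            detections += out.loc[0, "p"] < 0.001
        assert detections >= 19


class TestEligibility:
    def _counts_ann(self, n_wt, n_mut, ct="A"):
        rows = []
        for i in range(n_wt):
            rows.append({"sample_id": f"{ct}w{i}", "cancer_type": ct,
                         "tp53_status": "WT", "tp53_class": "WT"})
        for i in range(n_mut):
            rows.append({"sample_id": f"{ct}m{i}", "cancer_type": ct,
                         "tp53_status": "MUT", "tp53_class": "InframeMissense"})
        return _ann(rows)

    def test_strict_boundary(self):
        assert eligible_contexts(self._counts_ann(21, 21)) == ["A"]
        assert eligible_contexts(self._counts_ann(20, 50)) == []
        assert eligible_contexts(self._counts_ann(20, 50), inclusive=True) == ["A"]

    def test_unknown_class_does_not_count(self):
        ann = self._counts_ann(21, 21)
        ann.loc[ann.index[:2], "tp53_class"] = "Unknown"
        assert eligible_contexts(ann) == []


class TestDeltaCorrelation:
    def _profile(self, rhos, ct="A", stratum="WT"):
        tbl = pd.DataFrame(
            {"rho": rhos, "p": 0.5, "q": 0.5, "n_pairs": 30},
        ).rename_axis("gene")
        tbl.index = [f"g{i}" for i in range(len(rhos))]
        return CorrelationProfile(ct, stratum, "QG", tbl)

    def test_identical_strata_delta_zero(self):
        p = self._profile([0.1, -0.5, 0.9])
        out = delta_correlation(p, self._profile([0.1, -0.5, 0.9], stratum="MUT"))
        assert (out["delta"] == 0).all()
        assert not out["significant"].any()

    def test_antisymmetry(self):
        a = self._profile([0.1, -0.5, 0.9])
        b = self._profile([-0.7, 0.2, 0.4], stratum="MUT")
        fwd = delta_correlation(a, b)["delta"]
        rev = delta_correlation(b, a)["delta"]
        np.testing.assert_allclose(fwd, -rev, atol=1e-15)

    def test_missing_gene_excluded_and_counted(self):
        a = self._profile([0.1, np.nan, 0.9])
        b = self._profile([0.3, 0.2, 0.4], stratum="MUT")
        out = delta_correlation(a, b)
        assert "g1" not in out.index
        assert out.attrs["n_excluded"] == 1

    def test_cross_cancer_type_rejected(self):
        with pytest.raises(ValueError, match="same cancer type"):
            delta_correlation(self._profile([0.1], ct="A"), self._profile([0.1], ct="B"))

    def test_planted_switch_module_recovered(self, small_spec, small_cohort):
        expr, ann = small_cohort
        mods = small_spec.module_gene_ids()
        deltas = {}
        for ct in eligible_contexts(ann):
            sub = ann[ann.cancer_type == ct]
            profs = {}
            for stratum in ("WT", "MUT"):
                ids = sub.loc[sub.tp53_status == stratum, "sample_id"]
                profs[stratum] = spearman_profile(expr, "MAPT", ids, ct, stratum)
            deltas[ct] = delta_correlation(profs["WT"], profs["MUT"])
        union, matrix = delta_union(deltas)
        # rho flips -0.4 -> +0.4: true delta 0.8, recovered by most members
        hits = set(union) & set(mods["SWITCHMOD"])
        assert len(hits) >= 0.5 * len(mods["SWITCHMOD"])
        # stable-module genes have true delta 0; at ~40/stratum a rare
        # fluctuation past 0.6 is possible but should stay isolated
        assert len(set(union) & set(mods["POSMOD"])) <= 2
        assert matrix.shape[1] == len(deltas)


class TestDeltaNES:
    def _gsea(self, nes):
        return pd.DataFrame(
            {"nes": nes}, index=pd.Index([f"S{i}" for i in range(len(nes))], name="geneset")
        )

    def test_identical_zero_and_label_swap_negates(self):
        a, b = self._gsea([1.0, -2.0]), self._gsea([2.5, 0.5])
        assert (delta_nes(a, a)["delta"] == 0).all()
        fwd = delta_nes(a, b)
        rev = delta_nes(b, a)
        np.testing.assert_allclose(fwd["delta"], -rev["delta"])

    def test_two_thresholds(self):
        wt, mut = self._gsea([0.0, 0.0, 0.0]), self._gsea([0.5, 1.0, 3.0])
        out = delta_nes(wt, mut)
        assert list(out["significant"]) == [False, True, True]
        assert list(out["reported"]) == [False, False, True]

    def test_single_stratum_set_excluded(self):
        wt = self._gsea([1.0, 2.0])
        mut = self._gsea([1.0, np.nan])
        out = delta_nes(wt, mut)
        assert len(out) == 1 and out.attrs["n_excluded"] == 1
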