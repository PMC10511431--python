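"""From-scratch verification runs of every pipeline stage.

Each function regenerates its inputs from a seed, executes the relevant
stage and measures how well the planted truth is recovered (or how
exactly an engine matches an independent brute-force oracle). They back
both the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are the desk-scale study conditions of the package:
300-sample cancer types for screen-recovery checks, 2000 subjects for
the Cox/rate-ratio comparison, 50 replicate cohorts for geneset
enrichment power, 200 replicate draws for null calibration.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import consensus_cluster
from .coexpression import significant_genes, spearman_profile
from .datamodel import GeneSetCollection
from .gsea import enrichment_score, normalized_enrichment
from .pharmaco import drug_screen, mrna_protein_correlation
from .stats import bh_adjust, spearman_rho
from .stratification import delta_correlation
from .survival import cox_fit, survival_screen
from .synthetic import (
    ModuleSpec,
    SyntheticSpec,
    generate_cell_line_panel,
    generate_cohort,
)


# --- independent oracles (deliberately naive implementations) ---------------


def _oracle_spearman(x, y) -> float:
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[order[j]] == v[order[i]]:
                j += 1
            for k in range(i, j):
                ranks[order[k]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def _oracle_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pvals[i] * m / rank)
        q[i] = prev
    return q


def _oracle_es(scores, flags, exponent):
    n = len(scores)
    nh = sum(flags)
    denom = sum(abs(s) ** exponent for s, h in zip(scores, flags) if h)
    run, best = 0.0, 0.0
    for s, h in zip(scores, flags):
        run += (abs(s) ** exponent / denom) if h else -1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


# --- criterion checks -------------------------------------------------------


def correlation_engine_check(seed: int) -> dict:
    """Spearman rho and BH q against brute-force oracles (exactness)."""
    rng = np.random.default_rng(seed)
    worst_rho = 0.0
    for _ in range(25):
        n = int(rng.integers(5, 25))
        x = rng.integers(0, 6, n).astype(float)  # ties on purpose
        y = rng.normal(size=n)
        worst_rho = max(worst_rho, abs(spearman_rho(x, y) - _oracle_spearman(x, y)))
    worst_bh = 0.0
    for _ in range(25):
        p = rng.uniform(0, 1, int(rng.integers(1, 40)))
        worst_bh = max(worst_bh, float(np.max(np.abs(bh_adjust(p) - _oracle_bh(list(p))))))
    return {"spearman_max_abs_diff": worst_rho, "bh_max_abs_diff": worst_bh, "n": 50}


def gsea_es_exactness(seed: int) -> dict:
    """ES against direct running-sum enumeration on short lists."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    cases = 0
    for exponent in (0.0, 1.0):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(n, size=k, replace=False).tolist())
            ranked = pd.Series(scores, index=[f"g{i}" for i in range(n)])
            es, _ = enrichment_score(ranked, {f"g{i}" for i in members}, exponent)
            flags = [i in members for i in range(n)]
            worst = max(worst, abs(es - _oracle_es(scores, flags, exponent)))
            cases += 1
    return {"max_abs_diff": worst, "n": cases}


def gsea_null_uniformity(seed: int, n_sets: int = 200, n_perm: int = 1000) -> dict:
    """Nominal p under the null: KS test against U(0,1) over replicate sets."""
    rng = np.random.default_rng(seed)
    pvals = []
    for rep in range(n_sets):
        scores = pd.Series(
            np.sort(rng.normal(size=400))[::-1], index=[f"g{i}" for i in range(400)]
        )
        members = rng.choice(scores.index, size=25, replace=False)
        coll = GeneSetCollection()
        coll.add("S", members)
        res = normalized_enrichment(
            scores, coll, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        pvals.append(float(res.loc["S", "p"]))
    ks = sps.kstest(pvals, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n": n_sets}


def gsea_planted_power(seed: int, n_reps: int = 50) -> dict:
    """Planted-positive sets (rho*=0.6, |S|=50, 500 samples): fraction of
    replicate cohorts with NES > 0 and FDR q < 0.001."""
    hits = 0
    for rep in range(n_reps):
        spec = SyntheticSpec(
            cancer_types=[("SOLO", 500)], n_genes=600,
            planted_modules=[ModuleSpec("POS", 50, rho=0.6)],
            seed=seed * 1000 + rep,
        )
        expr, ann = generate_cohort(spec)
        prof = spearman_profile(expr, spec.query_gene, ann["sample_id"], "SOLO")
        ranked = prof.table["rho"].dropna().sort_values(ascending=False)
        coll = GeneSetCollection()
        coll.add("PLANTED", spec.module_gene_ids()["POS"])
        rng = np.random.default_rng(seed * 77 + rep)
        for j in range(3):  # null companions give the FDR an observed tail
            coll.add(f"NULL{j}", rng.choice(ranked.index, 50, replace=False))
        res = normalized_enrichment(ranked, coll, n_perm=500, seed=seed + rep)
        hits += bool(
            res.loc["PLANTED", "nes"] > 0 and res.loc["PLANTED", "q"] < 0.001
        )
    return {"recovery_rate": hits / n_reps, "n": n_reps}


def module_recovery_check(seed: int, n: int = 300) -> dict:
    """|rho|>0.6 screen at planted rho*=0.7: module recovery and null FPR."""
    spec = SyntheticSpec(
        cancer_types=[("SOLO", n)], n_genes=2602,
        planted_modules=[ModuleSpec("POS", 300, rho=0.7)],
        seed=seed,
    )
    expr, ann = generate_cohort(spec)
    prof = spearman_profile(expr, spec.query_gene, ann["sample_id"], "SOLO")
    pos, neg = significant_genes(prof, threshold=0.6)
    hits = set(pos) | set(neg)
    module = set(spec.module_gene_ids()["POS"])
    nulls = {g for g in prof.table.index if g.startswith("NULL")}
    return {
        "module_recovery_rate": len(hits & module) / len(module),
        "null_fpr": len(hits & nulls) / len(nulls),
        "n": n,
    }


def delta_framework_check(seed: int, n_per_stratum: int = 300) -> dict:
    """Planted rho_WT=-0.4 / rho_MUT=+0.4 at 300/stratum: fraction of module
    genes beyond |delta|>0.6, plus exact antisymmetry."""
    spec = SyntheticSpec(
        cancer_types=[("SOLO", 2 * n_per_stratum)], n_genes=402,
        planted_modules=[ModuleSpec("SW", 100, rho_wt=-0.4, rho_mut=0.4)],
        mut_fraction=0.5, seed=seed,
    )
    expr, ann = generate_cohort(spec)
    profs = {}
    for stratum in ("WT", "MUT"):
        ids = ann.loc[ann["tp53_status"] == stratum, "sample_id"]
        profs[stratum] = spearman_profile(expr, spec.query_gene, ids, "SOLO", stratum)
    fwd = delta_correlation(profs["WT"], profs["MUT"], threshold=0.6)
    rev = delta_correlation(profs["MUT"], profs["WT"], threshold=0.6)
    anti = float(np.max(np.abs(fwd["delta"].to_numpy() + rev["delta"].to_numpy())))
    module = spec.module_gene_ids()["SW"]
    rate = float((fwd.loc[module, "delta"].abs() > 0.6).mean())
    return {"delta_recovery_rate": rate, "antisymmetry_max_abs_err": anti,
            "n": n_per_stratum}


def cox_engine_check(seed: int, n: int = 2000, n_reps: int = 30) -> dict:
    """Two-group exponential data, no censoring or ties: geometric-mean Cox
    HR against the closed-form rate-ratio MLE (d1/T1)/(d0/T0)."""
    log_cox, log_closed = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        g = (np.arange(n) % 2).astype(float)
        lam = 0.001 * np.exp(0.7 * g)
        t = rng.exponential(1.0 / lam)
        fit = cox_fit(pd.DataFrame({"g": g}), t, np.ones(n, bool))
        d1, t1 = (g == 1).sum(), t[g == 1].sum()
        d0, t0 = (g == 0).sum(), t[g == 0].sum()
        log_cox.append(np.log(fit.hr))
        log_closed.append(np.log((d1 / t1) / (d0 / t0)))
    rel_err = abs(np.exp(np.mean(log_cox) - np.mean(log_closed)) - 1.0)
    return {"rel_err": float(rel_err), "n": n}


def cox_recovery_check(seed: int, n: int = 1000, gamma: float = np.log(2.0)) -> dict:
    """Planted log-hazard recovery: median |log HR - gamma| over 5 cohorts
    of n=1000 with >= 300 events each."""
    errs, min_events = [], np.inf
    for rep in range(5):
        spec = SyntheticSpec(
            cancer_types=[("SOLO", n)], n_genes=20, planted_modules=[],
            survival_gamma=gamma, censoring_rate=0.1, seed=seed * 31 + rep,
        )
        expr, ann = generate_cohort(spec)
        grid = survival_screen(expr, ann, spec.query_gene, strata=("ALL",))
        uni = grid[grid["model"] == "univariate"].iloc[0]
        errs.append(abs(np.log(uni["hr"]) - gamma))
        min_events = min(min_events, uni["n_events"])
    return {"abs_err": float(np.median(errs)), "min_events": int(min_events), "n": n}


def survival_gate_check(seed: int) -> dict:
    """Constructed boundary cohorts: 9 events blank the univariate cell;
    covariates for only 19 patients blank the multivariate cell."""
    spec = SyntheticSpec(
        cancer_types=[("CT", 120)], n_genes=10, planted_modules=[],
        survival_gamma=0.0, censoring_rate=0.0, covariate_missing=0.0, seed=seed,
    )
    expr, ann = generate_cohort(spec)
    checks = []

    nine = ann.copy()
    nine["os_event"] = [i < 9 for i in range(len(nine))]
    grid = survival_screen(expr, nine, spec.query_gene, strata=("ALL",))
    uni = grid[grid["model"] == "univariate"].iloc[0]
    checks.append(not uni["eligible"] and np.isnan(uni["hr"]))

    ten = ann.copy()
    ten["os_event"] = [i < 10 for i in range(len(ten))]
    grid = survival_screen(expr, ten, spec.query_gene, strata=("ALL",))
    checks.append(bool(grid[grid["model"] == "univariate"].iloc[0]["eligible"]))

    sparse = ann.copy()
    sparse.loc[sparse.index[19:], ["size_stage", "node_stage", "met_stage", "aurka"]] = np.nan
    grid = survival_screen(expr, sparse, spec.query_gene, strata=("ALL",))
    multi = grid[grid["model"] == "multivariate"].iloc[0]
    checks.append(not multi["eligible"] and np.isnan(multi["hr"]))

    twenty = ann.copy()
    twenty.loc[twenty.index[20:], ["size_stage", "node_stage", "met_stage", "aurka"]] = np.nan
    grid = survival_screen(expr, twenty, spec.query_gene, strata=("ALL",))
    checks.append(bool(grid[grid["model"] == "multivariate"].iloc[0]["eligible"]))

    return {"all_gates_correct": float(all(checks)), "n": len(checks)}


def pharmaco_gate_check(seed: int) -> dict:
    """Eligibility truth table on an enumerated toy panel, and the
    AUC -> 1-AUC sign flip."""
    from .datamodel import CellLinePanel, ExpressionMatrix

    rng = np.random.default_rng(seed)

    expr_pool = rng.uniform(0.1, 3, 64)  # fixed expression; only AUC varies

    def panel_for(aucs):
        lines = [f"L{i}" for i in range(len(aucs))]
        meta = pd.DataFrame(
            {"cell_line": lines, "cancer_type": "A", "lineage": "tumour"}
        )
        expr = ExpressionMatrix(
            pd.DataFrame([expr_pool[: len(lines)]], index=["QG"], columns=lines)
        )
        auc = pd.DataFrame({"d": aucs}, index=lines)
        return CellLinePanel(expression=expr, meta=meta, auc=auc, auc_source={"d": "s"})

    correct = total = 0
    for n_sens, n_res, n_mid in itertools.product(range(4), repeat=3):
        n_lines = n_sens + n_res + n_mid
        if n_lines == 0:
            continue
        aucs = [0.2] * n_sens + [0.95] * n_res + [0.8] * n_mid
        row = drug_screen(panel_for(aucs), "QG", min_lines=3).iloc[0]
        expected = n_lines >= 3 and n_sens >= 2 and n_res >= 2
        correct += bool(row["eligible"]) == expected
        total += 1

    # both tails populated so the screen stays eligible after AUC -> 1-AUC
    aucs = np.concatenate([[0.1, 0.15, 0.9, 0.95], rng.uniform(0.05, 0.95, 16)])
    r1 = drug_screen(panel_for(list(aucs)), "QG").iloc[0]["rho"]
    r2 = drug_screen(panel_for(list(1 - aucs)), "QG").iloc[0]["rho"]
    return {
        "truth_table_accuracy": correct / total,
        "sign_flip_max_abs_err": abs(r1 + r2),
        "n": total,
    }


def consensus_check(seed: int) -> dict:
    """Two separated profile groups (10 items each, sd 0.6 vs separation 3):
    chosen k and the weakest within-group consensus at k=2."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.6, (10, 15)), rng.normal(3, 0.6, (10, 15))])
    prof = pd.DataFrame(X, index=[f"T{i}" for i in range(20)])
    res = consensus_cluster(prof, k_range=range(2, 6), reps=150, subsample=0.6,
                            seed=seed + 1)
    M = res.consensus[2].to_numpy()
    within = min(float(M[:10, :10].min()), float(M[10:, 10:].min()))
    return {"chosen_k": res.chosen_k, "within_block_min": within, "n": 20}


def protein_correlation_check(seed: int) -> dict:
    """Generator-default mRNA-protein coupling measured on a 375-line panel."""
    spec = SyntheticSpec(
        cancer_types=[("A", 4), ("B", 4), ("C", 4), ("D", 4)],
        n_genes=20, planted_modules=[], lines_per_type=93,
        n_engineered=2, n_fibroblast=1, seed=seed,
    )
    panel = generate_cell_line_panel(spec)
    res = mrna_protein_correlation(panel, spec.query_gene, list(panel.protein.index))
    return {"correlation": res["correlation"], "n": res["n"]}
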