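"""Mutation-status-stratified analyses.

Expression comparisons between TP53 status groups (two-sided two-sample
t-tests per cancer type), an eligibility gate on stratum sizes, and the
delta framework: per-gene delta correlation and per-geneset delta NES,
both oriented MUT - WT (a positive delta means a stronger association
with the query gene in mutant tumors).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coexpression import CorrelationProfile
from .datamodel import ExpressionMatrix, TP53_MUT, TP53_WT

logger = logging.getLogger(__name__)

DEFAULT_MIN_PER_GROUP = 20
DEFAULT_DELTA_THRESH = 0.6
DEFAULT_DELTA_NES_REPORT = 2.3


def compare_expression_by_status(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    query_gene: str,
    grouping: str = "status",
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Two-sided Student's t-test of query-gene expression between TP53
    groups, per cancer type.

    ``grouping``: "status" compares WT vs MUT; "class" compares WT,
    TruncatingHomDel and InframeMissense pairwise. Contexts with a group
    below ``min_per_group`` samples are skipped with a notice.
    Returns one row per (cancer type, group pair) with group means/SDs,
    the pooled-variance t statistic and p.
    """
    col = "tp53_status" if grouping == "status" else "tp53_class"
    levels = (
        [TP53_WT, TP53_MUT]
        if grouping == "status"
        else [TP53_WT, "TruncatingHomDel", "InframeMissense"]
    )
    q = expr.gene(query_gene)
    rows = []
    for ct, grp in annotations.groupby("cancer_type"):
        vals = {
            lev: q.reindex(grp.loc[grp[col] == lev, "sample_id"]).dropna().to_numpy()
            for lev in levels
        }
        for a, b in itertools.combinations(levels, 2):
            if len(vals[a]) < min_per_group or len(vals[b]) < min_per_group:
                logger.info("skipping %s %s-vs-%s: group below %d samples", ct, a, b, min_per_group)
                continue
            t, p = sps.ttest_ind(vals[a], vals[b], equal_var=True)
            rows.append(
                {
                    "cancer_type": ct,
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(vals[a]),
                    "n_b": len(vals[b]),
                    "mean_a": float(np.mean(vals[a])),
                    "mean_b": float(np.mean(vals[b])),
                    "sd_a": float(np.std(vals[a], ddof=1)),
                    "sd_b": float(np.std(vals[b], ddof=1)),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def eligible_contexts(
    annotations: pd.DataFrame,
    min_per_group: int = DEFAULT_MIN_PER_GROUP,
    inclusive: bool = False,
) -> list[str]:
    """Cancer types with more than ``min_per_group`` samples in *each* TP53
    status group (strict '>' by default; ``inclusive`` switches to '>=').

    Unknown-class samples do not count toward either stratum.
    """
    known = annotations[annotations["tp53_class"] != "Unknown"]
    out = []
    for ct, grp in known.groupby("cancer_type"):
        n_wt = int((grp["tp53_status"] == TP53_WT).sum())
        n_mut = int((grp["tp53_status"] == TP53_MUT).sum())
        ok = (n_wt >= min_per_group and n_mut >= min_per_group) if inclusive else (
            n_wt > min_per_group and n_mut > min_per_group
        )
        if ok:
            out.append(ct)
    return sorted(out)


def delta_correlation(
    profile_wt: CorrelationProfile,
    profile_mut: CorrelationProfile,
    threshold: float = DEFAULT_DELTA_THRESH,
) -> pd.DataFrame:
    """Per-gene delta rho = rho_MUT - rho_WT within one cancer type.

    Genes whose rho is defined in only one stratum are excluded (their
    count is reported in ``attrs["n_excluded"]``). ``significant`` marks
    |delta| > threshold.
    """
    if profile_wt.cancer_type != profile_mut.cancer_type:
        raise ValueError(
            "delta requires both profiles from the same cancer type, got "
            f"{profile_wt.cancer_type!r} vs {profile_mut.cancer_type!r}"
        )
    wt = profile_wt.table["rho"]
    mut = profile_mut.table["rho"]
    genes = wt.index.union(mut.index)
    wt = wt.reindex(genes)
    mut = mut.reindex(genes)
    both = wt.notna() & mut.notna()
    out = pd.DataFrame(
        {
            "rho_wt": wt[both],
            "rho_mut": mut[both],
            "delta": mut[both] - wt[both],
        }
    ).rename_axis("gene")
    out["significant"] = out["delta"].abs() > threshold
    out.attrs["cancer_type"] = profile_wt.cancer_type
    out.attrs["n_excluded"] = int((~both).sum())
    return out


def delta_union(deltas: dict[str, pd.DataFrame]) -> tuple[list[str], pd.DataFrame]:
    """Union of significant-delta genes across cancer types plus the
    gene-by-cancer delta matrix over the union."""
    union: set[str] = set()
    for tbl in deltas.values():
        union.update(tbl.index[tbl["significant"]])
    genes = sorted(union)
    matrix = pd.DataFrame(
        {ct: tbl["delta"].reindex(genes) for ct, tbl in deltas.items()}, index=genes
    )
    return genes, matrix


def delta_nes(
    gsea_wt: pd.DataFrame,
    gsea_mut: pd.DataFrame,
    delta_min_abs: float = DEFAULT_DELTA_THRESH,
    report_min_abs: float = DEFAULT_DELTA_NES_REPORT,
) -> pd.DataFrame:
    """Per-geneset delta NES = NES_MUT - NES_WT with the two thresholds:
    ``significant`` (|delta| > 0.6 by default) and ``reported``
    (|delta| > 2.3 by default, the figure-reporting rule).

    Genesets evaluated in only one stratum are excluded and counted in
    ``attrs["n_excluded"]``.
    """
    wt = gsea_wt["nes"]
    mut = gsea_mut["nes"]
    names = wt.index.union(mut.index)
    wt = wt.reindex(names)
    mut = mut.reindex(names)
    both = wt.notna() & mut.notna()
    out = pd.DataFrame(
        {
            "nes_wt": wt[both],
            "nes_mut": mut[both],
            "delta": mut[both] - wt[both],
        }
    ).rename_axis("geneset")
    out["significant"] = out["delta"].abs() > delta_min_abs
    out["reported"] = out["delta"].abs() > report_min_abs
    out.attrs["n_excluded"] = int((~both).sum())
    return out
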