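"""Per-context co-expression profiling of the query gene.

A *context* is a (cancer type, stratum) pair; the stratum is ALL or one of
the TP53 status groups. Within each context the query gene is correlated
(Spearman) against every retained gene, p-values are Benjamini–Hochberg
corrected within the context, and genes beyond a |rho| threshold (default
0.6) are called significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, STRATUM_ALL
from .stats import bh_adjust, spearman_profile_matrix, spearman_test

logger = logging.getLogger(__name__)

DEFAULT_MEAN_THRESH = 0.5
DEFAULT_SD_THRESH = 0.2
DEFAULT_RHO_THRESH = 0.6


@dataclass
class CorrelationProfile:
    """Query-gene correlation profile within one context.

    ``table`` is indexed by gene with columns rho, p, q, n_pairs; the query
    gene itself is excluded. Genes with undefined rho (zero variance or
    < 3 complete pairs) carry NaN and sit outside the BH family.
    """

    cancer_type: str
    stratum: str
    query_gene: str
    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def filter_genes(
    expr: ExpressionMatrix,
    groups: pd.Series | dict,
    mean_thresh: float = DEFAULT_MEAN_THRESH,
    sd_thresh: float = DEFAULT_SD_THRESH,
    query_gene: str | None = None,
) -> list[str]:
    """Expressed-gene filter: keep genes whose mean exceeds ``mean_thresh``
    AND whose sample SD exceeds ``sd_thresh`` in at least one cancer type
    (strict inequalities). The query gene is force-retained with a warning
    if it fails."""
    groups = pd.Series(groups)
    groups = groups[groups.index.isin(expr.sample_ids)]
    if groups.empty:
        raise ValueError("empty sample->cancer-type grouping")
    keep = pd.Series(False, index=expr.values.index)
    for _, samples in groups.groupby(groups).groups.items():
        sub = expr.values[list(samples)]
        if sub.shape[1] < 2:
            continue
        means = sub.mean(axis=1, skipna=True)
        sds = sub.std(axis=1, ddof=1, skipna=True)
        keep |= (means > mean_thresh) & (sds > sd_thresh)
    kept = list(expr.values.index[keep])
    if query_gene is not None and query_gene in expr.values.index and query_gene not in kept:
        logger.warning(
            "query gene %s fails the expression filter; force-retained", query_gene
        )
        kept.append(query_gene)
    return kept


def spearman_profile(
    expr: ExpressionMatrix,
    query_gene: str,
    sample_ids,
    cancer_type: str = "",
    stratum: str = STRATUM_ALL,
) -> CorrelationProfile:
    """Correlate the query gene with every other gene over the given
    samples; BH-correct within the context."""
    if query_gene not in expr.values.index:
        raise KeyError(f"query gene {query_gene!r} absent from expression matrix")
    sample_ids = [s for s in sample_ids if s in expr.values.columns]
    sub = expr.values[sample_ids]
    y = sub.loc[query_gene].to_numpy()
    if np.isfinite(y).sum() < 3:
        raise ValueError(
            f"context {cancer_type}/{stratum}: fewer than 3 observed query values"
        )
    others = sub.index[sub.index != query_gene]
    X = sub.loc[others].to_numpy()
    rho, p, n_pairs = spearman_profile_matrix(X, y)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"rho": rho, "p": p, "q": q, "n_pairs": n_pairs}, index=others
    ).rename_axis("gene")
    return CorrelationProfile(cancer_type, stratum, query_gene, table)


def significant_genes(
    profile: CorrelationProfile,
    threshold: float = DEFAULT_RHO_THRESH,
    require_q: float | None = None,
) -> tuple[list[str], list[str]]:
    """Genes with rho >= threshold (positive) / rho <= -threshold (negative).

    The screen is on the correlation magnitude alone; pass ``require_q`` to
    additionally demand BH significance.
    """
    tbl = profile.table
    mask = pd.Series(True, index=tbl.index)
    if require_q is not None:
        mask &= tbl["q"] < require_q
    pos = list(tbl.index[(tbl["rho"] >= threshold) & mask])
    neg = list(tbl.index[(tbl["rho"] <= -threshold) & mask])
    return pos, neg


def union_correlated_genes(
    profiles: list[CorrelationProfile],
    threshold: float = DEFAULT_RHO_THRESH,
) -> tuple[list[str], pd.DataFrame]:
    """Union over contexts of significant genes, plus the gene-by-cancer
    rho matrix restricted to that union (heatmap/clustering substrate)."""
    union: set[str] = set()
    for prof in profiles:
        pos, neg = significant_genes(prof, threshold)
        union.update(pos)
        union.update(neg)
    genes = sorted(union)
    rho_matrix = pd.DataFrame(
        {prof.cancer_type: prof.table["rho"].reindex(genes) for prof in profiles},
        index=genes,
    )
    return genes, rho_matrix


def counts_vs_level(
    counts: pd.DataFrame, mean_level: pd.Series
) -> dict[str, float]:
    """Spearman correlation of per-cancer significant-gene counts
    (columns total/positive/negative) against mean query expression.

    Returns NaN for a count column with zero variance.
    """
    common = counts.index.intersection(mean_level.index)
    if len(common) < 3:
        raise ValueError("need >= 3 cancer types")
    out = {}
    for col in ("total", "positive", "negative"):
        rho, _, _ = spearman_test(
            counts.loc[common, col].to_numpy(dtype=float),
            mean_level.loc[common].to_numpy(dtype=float),
        )
        out[col] = rho
    return out


def overlap_with_reference(genes, reference) -> tuple[list[str], int]:
    """Exact, order-stable intersection with an external reference list."""
    ref = set(reference)
    overlap = [g for g in genes if g in ref]
    return overlap, len(overlap)


def profile_contexts(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    query_gene: str,
    strata: tuple[str, ...] = (STRATUM_ALL,),
    min_samples: int = 3,
) -> list[CorrelationProfile]:
    """Profile every (cancer type, stratum) context with enough samples.

    Strata beyond ALL select on ``tp53_status``; Unknown-class samples are
    excluded from WT/MUT strata but retained in ALL.
    """
    profiles = []
    for ct, grp in annotations.groupby("cancer_type"):
        for stratum in strata:
            if stratum == STRATUM_ALL:
                samples = grp["sample_id"]
            else:
                sel = (grp["tp53_status"] == stratum) & (grp["tp53_class"] != "Unknown")
                samples = grp.loc[sel, "sample_id"]
            samples = [s for s in samples if s in expr.values.columns]
            if len(samples) < min_samples:
                logger.info("skipping context %s/%s (<%d samples)", ct, stratum, min_samples)
                continue
            profiles.append(spearman_profile(expr, query_gene, samples, ct, stratum))
    return profiles
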