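"""Pre-ranked geneset enrichment from first principles.

The enrichment score is the signed extremum of a weighted
Kolmogorov–Smirnov running sum over the ranked gene list: a hit at
position i increments by |score_i|^exponent normalized over the in-set
hits; a miss decrements by 1/(N - |hits|). The null is built by
size-preserving gene-label permutations of set membership (the phenotype
was consumed upstream when the list was ranked), NES divides ES by the
mean |permutation ES| of matching sign, and the FDR is the standard
signed ratio-of-tails estimate computed separately for positive and
negative NES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GeneSetCollection

DEFAULT_EXPONENT = 1.0
DEFAULT_N_PERM = 1000
DEFAULT_FDR_MAX = 0.001
DEFAULT_NES_MIN_ABS = 2.3


@dataclass
class EnrichmentResult:
    geneset: str
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    context: str = ""
    n_hits: int = 0
    n_perm: int = 0
    seed: int | None = None


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, exponent: float) -> np.ndarray:
    n = len(scores)
    n_hits = int(hit_mask.sum())
    weights = np.abs(scores) ** exponent
    hit_total = weights[hit_mask].sum()
    steps = np.where(
        hit_mask,
        weights / hit_total if hit_total > 0 else 1.0 / n_hits,
        -1.0 / (n - n_hits),
    )
    return np.cumsum(steps)


def enrichment_score(
    ranked: pd.Series | tuple,
    geneset,
    exponent: float = DEFAULT_EXPONENT,
) -> tuple[float, np.ndarray]:
    """ES of a geneset on a ranked list.

    ``ranked``: pandas Series of scores indexed by gene, ordered by
    decreasing score (e.g. correlation with the query gene). Returns
    (ES, running sum). The set must intersect the list and be a proper
    subset of it.
    """
    if not isinstance(ranked, pd.Series):
        genes, scores = ranked
        ranked = pd.Series(np.asarray(scores, float), index=list(genes))
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hit_mask = np.isin(genes, list(geneset))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("geneset is disjoint from the ranked list")
    if n_hits == len(genes):
        raise ValueError("geneset covers the entire ranked list (degenerate)")
    rs = _running_sum(scores, hit_mask, exponent)
    es = float(rs[np.argmax(np.abs(rs))])
    return es, rs


def _permutation_es(
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES distribution from size-preserving random membership draws."""
    n = len(scores)
    weights = np.abs(scores) ** exponent
    miss_step = -1.0
    out = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        w_hit = weights[mask]
        total = w_hit.sum()
        steps = np.where(
            mask,
            weights / total if total > 0 else 1.0 / set_size,
            miss_step / (n - set_size),
        )
        rs = np.cumsum(steps)
        out[k] = rs[np.argmax(np.abs(rs))]
    return out


def normalized_enrichment(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exponent: float = DEFAULT_EXPONENT,
    context: str = "",
    min_size: int = 2,
) -> pd.DataFrame:
    """ES/NES/p/q for every geneset of the collection on one ranked list.

    Returns a DataFrame indexed by geneset with columns es, nes, p, q,
    n_hits. Sets intersecting the list in fewer than ``min_size`` genes are
    dropped; a set with no same-sign permutation ES gets NaN NES.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows = {}
    perm_nes_all: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for name in collection.names:
        members = collection.sets[name]
        hit_mask = np.isin(genes, list(members))
        n_hits = int(hit_mask.sum())
        if n_hits < min_size or n_hits == len(genes):
            continue
        rs = _running_sum(scores, hit_mask, exponent)
        es = float(rs[np.argmax(np.abs(rs))])
        if n_hits not in null_cache:
            null_cache[n_hits] = _permutation_es(scores, n_hits, n_perm, exponent, rng)
        null = null_cache[n_hits]
        pos, neg = null[null > 0], null[null < 0]
        same_sign = pos if es > 0 else neg if es < 0 else null
        if same_sign.size == 0:
            rows[name] = (es, np.nan, np.nan, n_hits)
            perm_nes_all.append(np.array([]))
            continue
        nes = es / np.abs(same_sign).mean()
        # add-one smoothed same-sign tail probability
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        rows[name] = (es, nes, p, n_hits)
        # permutation NES: each sign normalized by its own mean magnitude
        perm_nes = np.empty_like(null)
        perm_nes[null > 0] = pos / pos.mean() if pos.size else 0.0
        perm_nes[null < 0] = neg / np.abs(neg).mean() if neg.size else 0.0
        perm_nes[null == 0] = 0.0
        perm_nes_all.append(perm_nes)

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["es", "nes", "p", "n_hits"]
    ).rename_axis("geneset")
    table["q"] = _fdr_signed(table["nes"].to_numpy(), perm_nes_all)
    table["n_perm"] = n_perm
    table["context"] = context
    return table[["es", "nes", "p", "q", "n_hits", "n_perm", "context"]]


def _fdr_signed(obs_nes: np.ndarray, perm_nes: list[np.ndarray]) -> np.ndarray:
    """Subramanian-style FDR: ratio of the permutation tail fraction to the
    observed tail fraction, positive and negative NES handled separately,
    capped at 1."""
    q = np.full(len(obs_nes), np.nan)
    all_perm = np.concatenate([p for p in perm_nes if p.size]) if perm_nes else np.array([])
    finite_obs = obs_nes[np.isfinite(obs_nes)]
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes) or all_perm.size == 0:
            continue
        if nes >= 0:
            perm_pos = all_perm[all_perm >= 0]
            perm_tail = np.mean(perm_pos >= nes) if perm_pos.size else 0.0
            obs_pos = finite_obs[finite_obs >= 0]
            obs_tail = np.mean(obs_pos >= nes) if obs_pos.size else 1.0
        else:
            perm_neg = all_perm[all_perm < 0]
            perm_tail = np.mean(perm_neg <= nes) if perm_neg.size else 0.0
            obs_neg = finite_obs[finite_obs < 0]
            obs_tail = np.mean(obs_neg <= nes) if obs_neg.size else 1.0
        q[i] = min(1.0, perm_tail / obs_tail) if obs_tail > 0 else np.nan
    return q


def significant_genesets(
    results: dict[str, pd.DataFrame] | pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    nes_min_abs: float = DEFAULT_NES_MIN_ABS,
) -> pd.DataFrame:
    """Pan-context reporting rule: a geneset is reported iff it passes
    q < fdr_max AND |NES| > nes_min_abs in at least one context; all
    per-context values of reported sets are retained (heatmap semantics).

    ``results``: {context: normalized_enrichment table} or a single table.
    """
    if isinstance(results, pd.DataFrame):
        results = {str(results["context"].iloc[0]) if len(results) else "": results}
    frames = []
    for ctx, tbl in results.items():
        t = tbl.copy()
        t["context"] = ctx
        frames.append(t.reset_index())
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["geneset", "es", "nes", "p", "q", "context"]
    )
    passing = combined[
        (combined["q"] < fdr_max) & (combined["nes"].abs() > nes_min_abs)
    ]["geneset"].unique()
    return combined[combined["geneset"].isin(passing)].reset_index(drop=True)


def assemble_collection(*collections: GeneSetCollection) -> GeneSetCollection:
    """Merge geneset collections (e.g. hallmark + pathway + custom + KO
    signatures); name collisions raise listing the offenders."""
    merged = GeneSetCollection()
    for coll in collections:
        merged = merged.merge(coll)
    return merged
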