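"""Consensus K-means clustering of cancer types by correlation profile.

Stability-based clustering: for each candidate k, items (cancer types)
are repeatedly subsampled and K-means (Euclidean, k-means++ init) is run
on each subsample; the consensus matrix entry for a pair is the fraction
of co-sampled runs in which the pair landed in the same cluster. The
number of clusters is chosen from the consensus CDF delta-area curve:
the largest k whose relative area increase still exceeds an elbow
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

DEFAULT_K_RANGE = range(2, 11)
DEFAULT_REPS = 1000
DEFAULT_SUBSAMPLE = 0.8
DEFAULT_ELBOW = 0.025
DEFAULT_PAC_BOUNDS = (0.1, 0.9)
DEFAULT_PAC_MAX = 0.1


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]
    area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int | None
    assignments: pd.Series | None
    degenerate: bool = False
    notes: str = ""


def _pac(consensus: np.ndarray, bounds=DEFAULT_PAC_BOUNDS) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal
    consensus entries strictly inside ``bounds`` (neither 'always together'
    nor 'never together')."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    lo, hi = bounds
    return float(np.mean((vals > lo) & (vals < hi))) if vals.size else 0.0


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    if vals.size == 0:
        return 0.0
    # CDF(x) = fraction of entries <= x; area over [0, 1]
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.concatenate([[0.0], (np.arange(len(vals)) + 1) / len(vals), [1.0]])
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_cluster(
    profiles: pd.DataFrame,
    k_range=DEFAULT_K_RANGE,
    reps: int = DEFAULT_REPS,
    subsample: float = DEFAULT_SUBSAMPLE,
    seed: int = 0,
    elbow: float = DEFAULT_ELBOW,
    pac_bounds: tuple[float, float] = DEFAULT_PAC_BOUNDS,
    pac_max: float = DEFAULT_PAC_MAX,
    n_init: int = 10,
    max_iter: int = 300,
) -> ConsensusResult:
    """Consensus K-means over item subsamples.

    ``profiles``: items (cancer types) x features (per-gene rho values);
    NaN features are imputed to the column median before clustering.
    Requires at least max(k_range) + 1 items.
    """
    k_range = list(k_range)
    items = list(profiles.index)
    n = len(items)
    if max(k_range) + 1 > n:
        raise ValueError(
            f"k_range up to {max(k_range)} needs at least {max(k_range) + 1} items, got {n}"
        )
    X = profiles.to_numpy(dtype=float)
    col_med = np.nanmedian(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = np.take(col_med, nan_c)

    if np.allclose(X, X[0], atol=1e-12):
        return ConsensusResult({}, {}, {}, {}, None, None, degenerate=True,
                               notes="all items identical; no cluster structure")

    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))
    if max(k_range) >= m:
        raise ValueError(
            f"k up to {max(k_range)} needs more than k items per subsample "
            f"(subsample draws {m} of {n}); lower k_max or raise the subsample fraction"
        )
    consensus, area = {}, {}
    for k in k_range:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(
                n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
                random_state=int(rng.integers(2**31 - 1)),
            )
            labels = km.fit_predict(X[idx])
            cosampled[np.ix_(idx, idx)] += 1
            for lab in range(k):
                members = idx[labels == lab]
                together[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore"):
            M = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = pd.DataFrame(M, index=items, columns=items)
        area[k] = _cdf_area(M)

    delta = {}
    ks = sorted(area)
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0

    pac = {k: _pac(consensus[k].to_numpy(), pac_bounds) for k in ks}
    # candidate ks clear the delta-area elbow; among those, an ambiguous
    # consensus matrix (high PAC) disqualifies a k — forcing extra clusters
    # onto within-cluster noise splits items arbitrarily between runs, which
    # keeps inflating the CDF area even past the true k
    candidates = [k for k in ks if delta[k] > elbow]
    crisp = [k for k in candidates if pac[k] <= pac_max]
    chosen = max(crisp) if crisp else (max(candidates) if candidates else None)
    assignments = None
    if chosen is not None:
        dist = 1.0 - consensus[chosen].to_numpy()
        model = AgglomerativeClustering(
            n_clusters=chosen, metric="precomputed", linkage="average"
        )
        assignments = pd.Series(model.fit_predict(dist), index=items, name="cluster")
    return ConsensusResult(consensus, area, delta, pac, chosen, assignments)
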