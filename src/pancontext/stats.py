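"""Rank-correlation and multiple-testing primitives shared by the pipeline.

Spearman's rho is Pearson correlation on mid-ranks (average ranks for
ties), so it is invariant under strictly monotone transforms of either
variable. Two-sided p-values use the t-approximation
t = rho * sqrt((n-2) / (1-rho^2)) for n > EXACT_N_MAX, and the exact
permutation distribution (full enumeration of the n! pairings) for the
tiny samples where the approximation is poorest.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Largest n for which the exact permutation null is fully enumerated
#: (8! = 40320 pairings; beyond that the t-approximation is accurate enough
#: and enumeration cost grows factorially).
EXACT_N_MAX = 8


def _all_permutations(n: int) -> np.ndarray:
    """All permutations of range(n), shape (n!, n), built iteratively."""
    perms = np.zeros((1, 1), dtype=np.int8)
    for m in range(2, n + 1):
        k = perms.shape[0]
        out = np.empty((k * m, m), dtype=np.int8)
        for pos in range(m):
            block = out[pos * k : (pos + 1) * k]
            block[:, pos] = m - 1
            block[:, :pos] = perms[:, :pos]
            block[:, pos + 1 :] = perms[:, pos:]
        perms = out
    return perms


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho on pairwise-complete observations (NaN if < 3 pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    rx = sps.rankdata(x[ok])
    ry = sps.rankdata(y[ok])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = len(rx)
    perms = _all_permutations(n)
    ry_perm = ry[perms]  # (n!, n) permuted rank vectors
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    rho_perm = (ry_perm - ry.mean()) @ xc / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho and two-sided p on pairwise-complete pairs.

    Returns (rho, p, n_pairs). rho and p are NaN when fewer than 3 complete
    pairs exist or either variable is constant in context.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    rx = sps.rankdata(x[ok])
    ry = sps.rankdata(y[ok])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan"), n
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        p = _exact_p(rx, ry, rho)
    else:
        p = _t_approx_p(np.array([rho]), n)[0]
    return rho, float(p), n


def _t_approx_p(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p from the t-approximation, vectorized; |rho|=1 -> p=0."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p = np.where(np.isfinite(rho), p, np.nan)
    return p


def spearman_profile_matrix(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spearman rho/p of every row of X against y, pairwise-complete.

    X is genes x samples (may contain NaN); y is the query vector over the
    same samples. Rows without missing data are ranked and correlated in one
    vectorized pass; rows with missingness fall back to the per-pair path.
    Returns (rho, p, n_pairs) arrays of length X.shape[0]; rho is NaN for
    rows with < 3 complete pairs or zero variance in context.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_genes, n_samples = X.shape
    rho = np.full(n_genes, np.nan)
    npairs = np.zeros(n_genes, dtype=int)

    y_ok = np.isfinite(y)
    ys = y[y_ok]
    n = int(y_ok.sum())
    fast_path = n >= 3 and ys.size > 0 and np.ptp(ys) > 0
    clean = ~np.isnan(X[:, y_ok]).any(axis=1) if fast_path else np.zeros(n_genes, bool)
    if fast_path and clean.any():
        ry = sps.rankdata(ys)
        RX = np.apply_along_axis(sps.rankdata, 1, X[np.ix_(clean, y_ok)])
        RXc = RX - RX.mean(axis=1, keepdims=True)
        ryc = ry - ry.mean()
        row_ss = (RXc**2).sum(axis=1)
        denom = np.sqrt(row_ss * (ryc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (RXc @ ryc) / denom
        r[row_ss == 0] = np.nan
        rho[clean] = r
        npairs[clean] = n
    # rows with missing values: pairwise-complete one at a time
    for i in np.flatnonzero(~clean):
        r, _, m = spearman_test(X[i], y)
        rho[i] = r
        npairs[i] = m
    p = np.full(n_genes, np.nan)
    small = (npairs <= EXACT_N_MAX) & np.isfinite(rho)
    big = (npairs > EXACT_N_MAX) & np.isfinite(rho)
    if big.any():
        p[big] = _t_approx_p(rho[big], npairs[big])
    for i in np.flatnonzero(small):
        _, pi, _ = spearman_test(X[i], y)
        p[i] = pi
    return rho, p, npairs


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries stay NaN and are
    excluded from the family."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
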