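"""Second-order analyses across cancer types.

For every gene (or geneset), its vector of per-cancer associations with
the query gene (rho, or NES) is correlated with the vector of per-cancer
hazard ratios from the univariate survival screen. A gene whose
co-expression with the query tracks the query's prognostic effect across
tumor types is a candidate mediator of that effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import spearman_rho

DEFAULT_MIN_CONTEXTS = 3


def _second_order(
    value_matrix: pd.DataFrame,
    hr_vector: pd.Series,
    min_contexts: int = DEFAULT_MIN_CONTEXTS,
    method: str = "spearman",
    log_hr: bool = False,
) -> pd.DataFrame:
    contexts = value_matrix.columns.intersection(hr_vector.index)
    if len(contexts) < min_contexts:
        raise ValueError(
            f"need >= {min_contexts} cancer types with both associations and "
            f"hazard ratios, got {len(contexts)}"
        )
    hr = hr_vector.loc[contexts].astype(float)
    if log_hr:
        hr = np.log(hr)
    vals = value_matrix[contexts]
    rows = []
    n_excluded = 0
    for unit, row in vals.iterrows():
        ok = row.notna() & hr.notna()
        n = int(ok.sum())
        if n < min_contexts:
            n_excluded += 1
            continue
        x = row[ok].to_numpy(dtype=float)
        y = hr[ok].to_numpy(dtype=float)
        if method == "spearman":
            r2 = spearman_rho(x, y)
        elif method == "pearson":
            r2 = float(np.corrcoef(x, y)[0, 1]) if np.ptp(x) > 0 and np.ptp(y) > 0 else np.nan
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"unit": unit, "r2": r2, "n_contexts": n})
    out = pd.DataFrame(rows, columns=["unit", "r2", "n_contexts"]).set_index("unit")
    out.attrs["n_excluded"] = n_excluded
    return out


def correlation_vs_hazard(
    rho_matrix: pd.DataFrame,
    hr_vector: pd.Series,
    min_contexts: int = DEFAULT_MIN_CONTEXTS,
    method: str = "spearman",
    log_hr: bool = False,
    bins: int = 20,
    cut: float = 0.5,
) -> dict:
    """Per-gene correlation between its rho vector and the HR vector.

    ``rho_matrix``: gene x cancer-type rho values (NaN = not profiled);
    ``hr_vector``: per-cancer univariate hazard ratio, used as printed
    unless ``log_hr``. Returns {"table", "hist_counts", "hist_edges",
    "n_above", "n_below"} where n_above/n_below count genes with
    r2 > cut / r2 < -cut.
    """
    table = _second_order(rho_matrix, hr_vector, min_contexts, method, log_hr)
    r2 = table["r2"].dropna()
    counts, edges = np.histogram(r2, bins=bins, range=(-1, 1))
    return {
        "table": table,
        "hist_counts": counts,
        "hist_edges": edges,
        "n_above": int((r2 > cut).sum()),
        "n_below": int((r2 < -cut).sum()),
    }


def nes_vs_hazard(
    nes_matrix: pd.DataFrame,
    hr_vector: pd.Series,
    min_contexts: int = DEFAULT_MIN_CONTEXTS,
    method: str = "spearman",
    log_hr: bool = False,
    bins: int = 20,
    cut: float = 0.5,
) -> dict:
    """Same second-order analysis with geneset NES vectors in place of
    per-gene correlations."""
    return correlation_vs_hazard(
        nes_matrix, hr_vector, min_contexts, method, log_hr, bins, cut
    )
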