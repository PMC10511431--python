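"""Cell-line screens: drug-response correlation and mRNA–protein check.

The drug screen correlates query-gene expression with the drug-response
AUC (0 = sensitive, 1 = resistant) per (compound, cancer type), but only
where the eligibility gate holds: at least 10 lines tested, at least two
sensitive (AUC < 0.8) and two resistant (AUC > 0.8). A positive rho
therefore means high expression tracks resistance. Compounds eligible in
enough cancer types make the reportable heatmap.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import CellLinePanel, ExpressionMatrix
from .stats import spearman_test

logger = logging.getLogger(__name__)

DEFAULT_AUC_CUT = 0.8
DEFAULT_MIN_LINES = 10
DEFAULT_MIN_EACH_CLASS = 2
DEFAULT_MIN_TYPES = 11
EXCLUDED_LINEAGES = ("Engineered", "Fibroblast")


def filter_panel(panel: CellLinePanel, min_lines_per_type: int = 2) -> CellLinePanel:
    """Drop engineered/fibroblast lines, then cancer types with fewer than
    ``min_lines_per_type`` remaining lines in the expression data."""
    meta = panel.meta
    keep = ~meta["lineage"].isin(EXCLUDED_LINEAGES)
    n_decoys = int((~keep).sum())
    meta = meta[keep]
    in_expr = meta["cell_line"].isin(panel.expression.sample_ids)
    meta = meta[in_expr]
    counts = meta.groupby("cancer_type")["cell_line"].count()
    kept_types = counts[counts >= min_lines_per_type].index
    meta = meta[meta["cancer_type"].isin(kept_types)]
    if meta.empty:
        raise ValueError("no cell lines left after filtering")
    logger.info(
        "panel filter: removed %d decoy lines; kept %d lines in %d cancer types",
        n_decoys, len(meta), len(kept_types),
    )
    lines = list(meta["cell_line"])
    expr = panel.expression.subset_samples(lines)
    auc = panel.auc.reindex(index=lines) if panel.auc is not None else None
    protein = panel.protein[lines] if panel.protein is not None else None
    return CellLinePanel(
        expression=expr, meta=meta.reset_index(drop=True),
        auc=auc, auc_source=dict(panel.auc_source), protein=protein,
    )


def drug_screen(
    panel: CellLinePanel,
    query_gene: str,
    auc_sens_cut: float = DEFAULT_AUC_CUT,
    min_lines: int = DEFAULT_MIN_LINES,
    min_each_class: int = DEFAULT_MIN_EACH_CLASS,
) -> pd.DataFrame:
    """Expression-vs-AUC Spearman screen per (compound, cancer type).

    Eligibility is evaluated on lines with an observed AUC for the
    compound; rho is computed only when eligible. Returns one row per
    (compound, cancer type) with n_lines, n_sensitive, n_resistant,
    eligible, rho, p.
    """
    if panel.auc is None:
        raise ValueError("panel has no drug-response data")
    if query_gene not in panel.expression.values.index:
        raise ValueError(f"query gene {query_gene!r} absent from panel expression")
    q = panel.expression.gene(query_gene)
    rows = []
    for ct, grp in panel.meta.groupby("cancer_type"):
        lines = [ln for ln in grp["cell_line"] if ln in panel.auc.index]
        auc_block = panel.auc.reindex(index=lines)
        for compound in panel.auc.columns:
            a = auc_block[compound]
            tested = a.dropna()
            n_tested = len(tested)
            n_sens = int((tested < auc_sens_cut).sum())
            n_res = int((tested > auc_sens_cut).sum())
            eligible = (
                n_tested >= min_lines
                and n_sens >= min_each_class
                and n_res >= min_each_class
            )
            rho = p = np.nan
            if eligible:
                expr_vals = q.reindex(tested.index).to_numpy()
                rho, p, _ = spearman_test(expr_vals, tested.to_numpy())
            rows.append(
                {
                    "compound": compound,
                    "source": panel.auc_source.get(compound, "unknown"),
                    "cancer_type": ct,
                    "n_lines": n_tested,
                    "n_sensitive": n_sens,
                    "n_resistant": n_res,
                    "eligible": eligible,
                    "rho": rho,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def reportable_compounds(
    screen: pd.DataFrame,
    min_types: int = DEFAULT_MIN_TYPES,
) -> tuple[list[str], pd.DataFrame]:
    """Compounds eligible in >= ``min_types`` cancer types, plus the
    compound x cancer-type rho matrix with NaN for ineligible pairs."""
    eligible = screen[screen["eligible"]]
    counts = eligible.groupby("compound")["cancer_type"].nunique()
    compounds = sorted(counts[counts >= min_types].index)
    matrix = (
        eligible[eligible["compound"].isin(compounds)]
        .pivot(index="compound", columns="cancer_type", values="rho")
        .reindex(compounds)
    )
    return compounds, matrix


def mrna_protein_correlation(
    panel: CellLinePanel,
    query_gene: str,
    protein_ids: list[str],
    method: str = "pearson",
) -> dict:
    """Correlation of query mRNA with the summed protein isoform channels.

    Returns {"correlation", "n", "scatter"} where scatter is the per-line
    (mrna, protein) table over complete pairs.
    """
    if panel.protein is None:
        raise ValueError("panel has no proteomic data")
    missing = [p for p in protein_ids if p not in panel.protein.index]
    if missing:
        raise ValueError(f"protein channels absent: {missing}")
    protein = panel.protein.loc[protein_ids].sum(axis=0)
    mrna = panel.expression.gene(query_gene)
    common = protein.index.intersection(mrna.index)
    df = pd.DataFrame({"mrna": mrna.reindex(common), "protein": protein.reindex(common)}).dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 lines with both mRNA and protein measurements")
    if method == "pearson":
        cor = float(np.corrcoef(df["mrna"], df["protein"])[0, 1])
    elif method == "spearman":
        cor, _, _ = spearman_test(df["mrna"].to_numpy(), df["protein"].to_numpy())
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"correlation": cor, "n": len(df), "scatter": df}
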