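"""Shared data model for the pan-cancer association pipeline.

The pipeline charts the association landscape of a single *query gene*
(MAPT in the motivating application) across many cancer types: which genes
and pathways co-express with it, how TP53 mutation status reshapes those
associations, whether its expression predicts overall survival, and whether
it tracks drug response in cell-line panels.

All expression values are on a log scale (the cohort convention is
log10(FPKM + 1), so finite values are non-negative). Missing measurements
are carried as NaN and handled pairwise-complete downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TP53_WT = "WT"
TP53_MUT = "MUT"
TP53_CLASS_WT = "WT"
TP53_CLASS_TRUNC = "TruncatingHomDel"
TP53_CLASS_INFRAME = "InframeMissense"
TP53_CLASS_UNKNOWN = "Unknown"

STRATUM_ALL = "ALL"


class ExpressionMatrix:
    """Gene-by-sample matrix of log-scale expression.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and sample identifiers as
        columns. Missing cells are NaN.

    Invariants: unique gene and sample identifiers; every finite value >= 0
    under the log10(x + 1) convention.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:10]}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:10]}")
        arr = values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and finite.min() < 0:
            raise ValueError(
                "negative expression value; expected log10(x+1)-scale data (all values >= 0)"
            )
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the measurement is missing."""
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        if self.gene_ids != other.gene_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all(both_nan | np.isclose(a, b, rtol=0, atol=1e-12)))

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


#: Columns of the per-sample clinical annotation table. ``os_time`` is overall
#: survival in days; ordinal staging codes and covariate expression slots may
#: be missing (NaN).
ANNOTATION_COLUMNS = [
    "sample_id",
    "cancer_type",
    "tp53_status",
    "tp53_class",
    "os_time",
    "os_event",
    "size_stage",
    "node_stage",
    "met_stage",
]


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical annotation contract and return the frame.

    tp53_class == WT iff tp53_status == WT (when the class is known), and a
    missing survival time implies a missing event indicator.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in annotation table")
    known = ann["tp53_class"].notna() & (ann["tp53_class"] != TP53_CLASS_UNKNOWN)
    wt_mismatch = known & (
        (ann["tp53_class"] == TP53_CLASS_WT) != (ann["tp53_status"] == TP53_WT)
    )
    if wt_mismatch.any():
        bad = ann.loc[wt_mismatch, "sample_id"].tolist()
        raise ValueError(f"tp53_class/tp53_status inconsistent for samples {bad[:10]}")
    t_missing = ann["os_time"].isna()
    if (t_missing & ann["os_event"].notna()).any():
        raise ValueError("os_event present where os_time is missing")
    times = ann["os_time"].dropna()
    if (times < 0).any():
        raise ValueError("negative survival time")
    return ann


@dataclass
class GeneSetCollection:
    """Named, non-empty genesets with a provenance label per set."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"geneset {name!r} is empty")
        for name in self.sets:
            self.provenance.setdefault(name, "unknown")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def add(self, name: str, genes, provenance: str = "unknown") -> None:
        if name in self.sets:
            raise ValueError(f"geneset name collision: {name!r}")
        genes = frozenset(genes)
        if not genes:
            raise ValueError(f"geneset {name!r} is empty")
        self.sets[name] = genes
        self.provenance[name] = provenance

    def merge(self, other: "GeneSetCollection") -> "GeneSetCollection":
        collisions = sorted(set(self.sets) & set(other.sets))
        if collisions:
            raise ValueError(f"geneset name collisions: {collisions}")
        merged = GeneSetCollection(dict(self.sets), dict(self.provenance))
        for name in other.names:
            merged.add(name, other.sets[name], other.provenance[name])
        return merged

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


@dataclass
class CellLinePanel:
    """Cell-line panel: expression, metadata, drug response and proteomics.

    ``expression``: gene-by-line log-scale matrix (ExpressionMatrix).
    ``meta``: per-line table with columns ``cell_line``, ``cancer_type``,
    ``lineage`` (free label; "Engineered"/"Fibroblast" flag decoy lines).
    ``auc``: line-by-compound drug response, values in [0, 1]
    (0 = sensitive, 1 = resistant), NaN = not tested; a ``source`` row
    attribute is kept per compound in ``auc_source``.
    ``protein``: optional protein-channel-by-line abundance matrix.
    """

    expression: ExpressionMatrix
    meta: pd.DataFrame
    auc: pd.DataFrame | None = None
    auc_source: dict[str, str] = field(default_factory=dict)
    protein: pd.DataFrame | None = None

    def __post_init__(self):
        for col in ("cell_line", "cancer_type", "lineage"):
            if col not in self.meta.columns:
                raise ValueError(f"panel metadata missing column {col!r}")
        if self.meta["cell_line"].duplicated().any():
            raise ValueError("duplicate cell_line in metadata")
        known = set(self.meta["cell_line"])
        unknown = [s for s in self.expression.sample_ids if s not in known]
        if unknown:
            raise ValueError(f"expression lines absent from metadata: {unknown[:10]}")
        if self.auc is not None:
            bad_lines = [ln for ln in self.auc.index if ln not in known]
            if bad_lines:
                raise ValueError(f"AUC lines absent from metadata: {bad_lines[:10]}")
            vals = self.auc.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("AUC values outside [0, 1]")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.meta["cell_line"])
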