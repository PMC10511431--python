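"""Readers and writers for the external table formats.

Two expression dialects are supported: the pan-cancer cohort layout
(genes in rows, one header row of sample barcodes, tab-separated) and the
cell-line layout (samples in rows, genes in columns). GMT genesets follow
the MSigDB convention: name, description, then one gene per field.

Writers emit LF line endings and quote only when needed, so
write(read(x)) round-trips bit-exactly on files this module produced.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ANNOTATION_COLUMNS,
    CellLinePanel,
    ExpressionMatrix,
    GeneSetCollection,
    validate_annotations,
)

GENES_IN_ROWS = "genes_in_rows"
SAMPLES_IN_ROWS = "samples_in_rows"


def _dedupe_by_mean(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene symbols keeping the row with highest mean
    expression (deterministic; ties broken by first occurrence)."""
    if not df.index.duplicated().any():
        return df
    means = df.mean(axis=1, skipna=True).fillna(-np.inf).to_numpy()
    best: dict[str, tuple[float, int]] = {}
    for pos, (gene, m) in enumerate(zip(df.index, means)):
        if gene not in best or m > best[gene][0]:
            best[gene] = (m, pos)
    keep = sorted(pos for _, pos in best.values())
    return df.iloc[keep]


def read_expression_matrix(
    path, orientation: str = GENES_IN_ROWS, sep: str = "\t"
) -> ExpressionMatrix:
    """Read a delimited expression table into a gene-by-sample matrix.

    Empty or non-numeric cells become NaN (masked). Duplicate gene symbols
    are collapsed to the highest-mean row; duplicate sample identifiers are
    an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed expression file {path.name}: {exc}") from exc
    if df.columns.size == 0:
        raise ValueError(f"malformed header in {path.name}: no sample columns")
    df = df.apply(pd.to_numeric, errors="coerce")
    if orientation == SAMPLES_IN_ROWS:
        df = df.T
    elif orientation != GENES_IN_ROWS:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = _dedupe_by_mean(df)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers in {path.name}: {dups[:10]}")
    return ExpressionMatrix(df)


def write_expression_matrix(
    matrix: ExpressionMatrix, path, orientation: str = GENES_IN_ROWS, sep: str = "\t"
) -> None:
    df = matrix.values if orientation == GENES_IN_ROWS else matrix.values.T
    df.to_csv(path, sep=sep, lineterminator="\n", na_rep="")


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, dtype={"sample_id": str, "cancer_type": str},
                      float_precision="round_trip")
    if "os_event" in ann.columns:
        ann["os_event"] = ann["os_event"].map(
            lambda v: bool(int(v)) if pd.notna(v) else np.nan
        )
    return validate_annotations(ann)


def write_annotations(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out["os_event"] = out["os_event"].map(
        lambda v: int(v) if pd.notna(v) else np.nan
    )
    cols = ANNOTATION_COLUMNS + [c for c in out.columns if c not in ANNOTATION_COLUMNS]
    out[cols].to_csv(path, index=False, lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT geneset file (name, description, genes...)."""
    path = Path(path)
    coll = GeneSetCollection()
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs name, description "
                    f"and at least one gene (got {len(fields)} fields)"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path.name}:{lineno}: geneset {name!r} has no genes")
            if name in coll:
                raise ValueError(f"{path.name}:{lineno}: duplicate geneset name {name!r}")
            coll.add(name, genes, provenance=desc or "unknown")
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in coll.names:
            genes = sorted(coll.sets[name])
            desc = coll.provenance.get(name, "unknown")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# --- TP53 status classification -------------------------------------------

#: Default mapping from variant-class vocabulary to functional group.
#: Truncating lesions and homozygous deletions abolish the protein; missense
#: and in-frame lesions leave a (possibly neomorphic) full-length protein.
DEFAULT_VARIANT_CLASSES: dict[str, str | None] = {
    "missense": "InframeMissense",
    "inframe_indel": "InframeMissense",
    "nonsense": "TruncatingHomDel",
    "frameshift": "TruncatingHomDel",
    "splice": "TruncatingHomDel",
    "silent": None,  # non-functional change
    "none": None,
}

_CNA_VOCAB = {"homozygous_deletion", "other", "none"}
_SEVERITY = {"TruncatingHomDel": 2, "InframeMissense": 1}


def classify_tp53(
    mutation_records: dict[str, list[str]],
    cna_records: dict[str, str] | None = None,
    class_map: dict[str, str | None] | None = None,
) -> pd.DataFrame:
    """Classify per-sample TP53 status from variant calls and CNA.

    A sample is MUT iff it carries any non-silent variant or a homozygous
    deletion. Functional class follows severity precedence
    TruncatingHomDel > InframeMissense; classification is independent of
    record order. Unknown variant-class strings raise (no silent coercion).

    Returns a DataFrame indexed by sample with columns
    ``tp53_status`` and ``tp53_class``.
    """
    class_map = DEFAULT_VARIANT_CLASSES if class_map is None else class_map
    cna_records = cna_records or {}
    rows = {}
    samples = sorted(set(mutation_records) | set(cna_records))
    for sample in samples:
        severity = 0
        for var in mutation_records.get(sample, []):
            if var not in class_map:
                raise ValueError(f"unknown TP53 variant class {var!r} for {sample!r}")
            group = class_map[var]
            if group is not None:
                severity = max(severity, _SEVERITY[group])
        cna = cna_records.get(sample, "none")
        if cna not in _CNA_VOCAB:
            raise ValueError(f"unknown CNA call {cna!r} for {sample!r}")
        if cna == "homozygous_deletion":
            severity = max(severity, _SEVERITY["TruncatingHomDel"])
        if severity == 0:
            rows[sample] = ("WT", "WT")
        else:
            klass = "TruncatingHomDel" if severity == 2 else "InframeMissense"
            rows[sample] = ("MUT", klass)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["tp53_status", "tp53_class"]
    ).rename_axis("sample_id")


def build_ko_signature(
    de_table: pd.DataFrame,
    n: int = 100,
    effect_col: str = "log2fc",
    sig_col: str | None = "padj",
    sig_max: float = 0.05,
    gene_col: str = "gene",
    name_prefix: str = "QUERY_KO_VS_WT",
) -> GeneSetCollection:
    """Build UP/DOWN knock-out signature genesets from a DE result table.

    UP = top ``n`` significant genes by decreasing effect size, DOWN = top
    ``n`` by increasing. Significance gate applies when ``sig_col`` is given.
    Raises if either side has fewer than ``n`` rankable genes.
    """
    df = de_table.dropna(subset=[gene_col, effect_col]).copy()
    if sig_col is not None and sig_col in df.columns:
        df = df[df[sig_col] <= sig_max]
    df = df.sort_values([effect_col, gene_col], ascending=[False, True])
    up = df[df[effect_col] > 0].head(n)
    down = df[df[effect_col] < 0].sort_values(
        [effect_col, gene_col], ascending=[True, True]
    ).head(n)
    if len(up) < n or len(down) < n:
        raise ValueError(
            f"insufficient genes for KO signature: {len(up)} up, {len(down)} down, need {n} each"
        )
    coll = GeneSetCollection()
    coll.add(f"{name_prefix}_UP", up[gene_col], provenance="ko_signature")
    coll.add(f"{name_prefix}_DOWN", down[gene_col], provenance="ko_signature")
    return coll


# --- Cell-line panel ingestion ---------------------------------------------


def read_cell_line_panel(
    expression_path,
    meta_path,
    auc_paths: dict[str, str] | None = None,
    protein_path=None,
) -> CellLinePanel:
    """Assemble a CellLinePanel from its on-disk pieces.

    ``auc_paths`` maps a source label (e.g. "sanger", "prism") to a CSV with
    columns cell_line, compound, auc; response values must already be on the
    [0, 1] AUC scale (0 = sensitive). Compounds are not merged across
    sources: the compound key is "<source>:<compound>".
    """
    expr = read_expression_matrix(expression_path, orientation=SAMPLES_IN_ROWS, sep=",")
    meta = pd.read_csv(meta_path, dtype=str)
    auc = None
    auc_source: dict[str, str] = {}
    if auc_paths:
        frames = []
        for source, path in auc_paths.items():
            tbl = pd.read_csv(path, float_precision="round_trip")
            tbl["compound"] = source + ":" + tbl["compound"].astype(str)
            frames.append(tbl[["cell_line", "compound", "auc"]])
            for comp in frames[-1]["compound"].unique():
                auc_source[comp] = source
        long = pd.concat(frames, ignore_index=True)
        auc = long.pivot_table(index="cell_line", columns="compound", values="auc")
    protein = None
    if protein_path is not None:
        protein = pd.read_csv(protein_path, index_col=0, float_precision="round_trip")
        protein.columns = protein.columns.astype(str)
    return CellLinePanel(
        expression=expr, meta=meta, auc=auc, auc_source=auc_source, protein=protein
    )


def write_cell_line_panel(panel: CellLinePanel, out_dir) -> dict[str, Path]:
    """Write a panel to ``out_dir`` in the dialects ``read_cell_line_panel``
    accepts; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["expression"] = out_dir / "cell_line_expression.csv"
    write_expression_matrix(
        panel.expression, paths["expression"], orientation=SAMPLES_IN_ROWS, sep=","
    )
    paths["meta"] = out_dir / "cell_line_meta.csv"
    panel.meta.to_csv(paths["meta"], index=False, lineterminator="\n")
    if panel.auc is not None:
        long = panel.auc.stack().rename("auc").reset_index()
        long.columns = ["cell_line", "compound", "auc"]
        long["source"] = long["compound"].map(panel.auc_source).fillna("unknown")
        long["compound"] = long["compound"].str.split(":", n=1).str[-1]
        for source, grp in long.groupby("source"):
            p = out_dir / f"drug_response_{source}.csv"
            grp[["cell_line", "compound", "auc"]].to_csv(
                p, index=False, lineterminator="\n"
            )
            paths[f"auc_{source}"] = p
    if panel.protein is not None:
        paths["protein"] = out_dir / "protein_abundance.csv"
        panel.protein.to_csv(paths["protein"], lineterminator="\n")
    return paths
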