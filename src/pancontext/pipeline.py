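"""Pipeline orchestration from a single declarative config.

Stages run in dependency order (filter -> coexpr -> gsea -> stratify ->
survive -> meta/cluster -> pharmaco). A stage failure halts its
dependents but independent stages continue; every output file is listed
in a manifest with a content hash so identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import coexpression, gsea, io, meta, pharmaco, stratification, survival
from .datamodel import STRATUM_ALL

logger = logging.getLogger(__name__)

STAGE_DEPS = {
    "coexpr": [],
    "gsea": ["coexpr"],
    "stratify": ["coexpr"],
    "survive": [],
    "meta": ["coexpr", "survive"],
    "cluster": ["coexpr"],
    "pharmaco": [],
}


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds for one pipeline run.

    Threshold defaults are the screening rules of the cohort analysis the
    package implements: |rho| 0.6 for the gene screen, FDR < 0.001 with
    |NES| > 2.3 for genesets, delta thresholds 0.6 (significance) and 2.3
    (reporting), >= 10 events and 3-of-4 covariates in >= 20 patients for
    survival, and the 10-line / 2-sensitive / 2-resistant AUC-0.8 gate
    for the drug screen.
    """

    expression: str = ""
    clinical: str = ""
    query_gene: str = "MAPT"
    gmt_files: list[str] = field(default_factory=list)
    panel_dir: str = ""
    out_dir: str = "pancontext_out"
    stages: list[str] = field(
        default_factory=lambda: ["coexpr", "gsea", "stratify", "survive", "meta", "cluster", "pharmaco"]
    )
    rho_threshold: float = 0.6
    mean_thresh: float = 0.5
    sd_thresh: float = 0.2
    gsea_fdr_max: float = 0.001
    gsea_nes_min_abs: float = 2.3
    gsea_n_perm: int = 1000
    delta_threshold: float = 0.6
    delta_nes_report: float = 2.3
    strat_min_per_group: int = 20
    min_events: int = 10
    min_covar_patients: int = 20
    pharmaco_min_lines: int = 10
    pharmaco_min_each_class: int = 2
    auc_cut: float = 0.8
    cluster_k_max: int = 10
    cluster_reps: int = 200
    seed: int = 0

    def __post_init__(self):
        for name, val in (
            ("rho_threshold", self.rho_threshold),
            ("gsea_fdr_max", self.gsea_fdr_max),
            ("gsea_nes_min_abs", self.gsea_nes_min_abs),
            ("delta_threshold", self.delta_threshold),
            ("auc_cut", self.auc_cut),
        ):
            if val <= 0:
                raise ValueError(f"threshold {name} must be positive, got {val}")
        unknown = [s for s in self.stages if s not in STAGE_DEPS]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_inputs(self) -> None:
        """Fail fast: every enabled stage's inputs must resolve."""
        needs_cohort = any(s in self.stages for s in ("coexpr", "gsea", "stratify", "survive", "meta", "cluster"))
        if needs_cohort:
            for label, p in (("expression", self.expression), ("clinical", self.clinical)):
                if not p or not Path(p).exists():
                    raise FileNotFoundError(f"{label} input not found: {p!r}")
        if "gsea" in self.stages:
            for p in self.gmt_files:
                if not Path(p).exists():
                    raise FileNotFoundError(f"GMT file not found: {p!r}")
        if "pharmaco" in self.stages:
            if not self.panel_dir or not Path(self.panel_dir).is_dir():
                raise FileNotFoundError(f"panel directory not found: {self.panel_dir!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict (also written
    to ``<out_dir>/manifest.json``). Raises nothing on individual stage
    failure; failed stages and their skipped dependents are listed in the
    manifest with status."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    outputs: dict[str, list[str]] = {}
    state: dict = {}

    def save(stage: str, name: str, df: pd.DataFrame, index=True):
        path = out / name
        df.to_csv(path, sep="\t", index=index, lineterminator="\n")
        outputs.setdefault(stage, []).append(name)

    def runnable(stage: str) -> bool:
        for dep in STAGE_DEPS[stage]:
            if dep in config.stages and status.get(dep) != "ok":
                status[stage] = f"skipped: dependency {dep} not satisfied"
                return False
            if dep not in config.stages:
                status[stage] = f"skipped: dependency {dep} disabled"
                return False
        return True

    expr = ann = None
    if any(s in config.stages for s in ("coexpr", "gsea", "stratify", "survive", "meta", "cluster")):
        expr = io.read_expression_matrix(config.expression)
        ann = io.read_annotations(config.clinical)

    for stage in [s for s in STAGE_DEPS if s in config.stages]:
        if not runnable(stage):
            continue
        try:
            if stage == "coexpr":
                groups = ann.set_index("sample_id")["cancer_type"]
                kept = coexpression.filter_genes(
                    expr, groups, config.mean_thresh, config.sd_thresh, config.query_gene
                )
                fexpr = expr.subset_genes(kept)
                state["expr"] = fexpr
                profiles = coexpression.profile_contexts(fexpr, ann, config.query_gene)
                state["profiles"] = profiles
                counts = []
                for prof in profiles:
                    save("coexpr", f"profile_{prof.cancer_type}_{prof.stratum}.tsv", prof.table)
                    pos, neg = coexpression.significant_genes(prof, config.rho_threshold)
                    counts.append(
                        {"cancer_type": prof.cancer_type, "positive": len(pos),
                         "negative": len(neg), "total": len(pos) + len(neg)}
                    )
                union, rho_matrix = coexpression.union_correlated_genes(profiles, config.rho_threshold)
                state["rho_matrix_union"] = rho_matrix
                state["rho_matrix_all"] = pd.DataFrame(
                    {p.cancer_type: p.table["rho"] for p in profiles}
                )
                save("coexpr", "significant_counts.tsv", pd.DataFrame(counts), index=False)
                save("coexpr", "union_rho_matrix.tsv", rho_matrix)
            elif stage == "gsea":
                colls = [io.read_gmt(p) for p in config.gmt_files]
                collection = gsea.assemble_collection(*colls)
                results = {}
                nes_cols = {}
                for prof in state["profiles"]:
                    if prof.stratum != STRATUM_ALL:
                        continue
                    ranked = prof.table["rho"].dropna().sort_values(ascending=False)
                    tbl = gsea.normalized_enrichment(
                        ranked, collection, n_perm=config.gsea_n_perm,
                        seed=config.seed, context=prof.cancer_type,
                    )
                    results[prof.cancer_type] = tbl
                    nes_cols[prof.cancer_type] = tbl["nes"]
                    save("gsea", f"gsea_{prof.cancer_type}.tsv", tbl)
                state["gsea"] = results
                state["nes_matrix"] = pd.DataFrame(nes_cols)
                reported = gsea.significant_genesets(
                    results, config.gsea_fdr_max, config.gsea_nes_min_abs
                )
                save("gsea", "gsea_reported.tsv", reported, index=False)
            elif stage == "stratify":
                ttests = stratification.compare_expression_by_status(
                    state.get("expr", expr), ann, config.query_gene
                )
                save("stratify", "expression_by_status.tsv", ttests, index=False)
                eligible = stratification.eligible_contexts(ann, config.strat_min_per_group)
                fexpr = state.get("expr", expr)
                deltas = {}
                for ct in eligible:
                    sub_ann = ann[ann["cancer_type"] == ct]
                    profs = {}
                    for stratum in ("WT", "MUT"):
                        sel = (sub_ann["tp53_status"] == stratum) & (sub_ann["tp53_class"] != "Unknown")
                        profs[stratum] = coexpression.spearman_profile(
                            fexpr, config.query_gene, sub_ann.loc[sel, "sample_id"], ct, stratum
                        )
                    tbl = stratification.delta_correlation(
                        profs["WT"], profs["MUT"], config.delta_threshold
                    )
                    deltas[ct] = tbl
                    save("stratify", f"delta_rho_{ct}.tsv", tbl)
                union, dmat = stratification.delta_union(deltas)
                save("stratify", "delta_union_matrix.tsv", dmat)
            elif stage == "survive":
                grid = survival.survival_screen(
                    expr, ann, config.query_gene,
                    min_events=config.min_events,
                    min_covar_patients=config.min_covar_patients,
                )
                state["survival"] = grid
                save("survive", "survival_grid.tsv", grid, index=False)
            elif stage == "meta":
                grid = state["survival"]
                uni = grid[(grid["stratum"] == STRATUM_ALL) & (grid["model"] == "univariate")]
                hr = uni.set_index("cancer_type")["hr"].dropna()
                res = meta.correlation_vs_hazard(state["rho_matrix_all"], hr)
                save("meta", "gene_r2_vs_hazard.tsv", res["table"])
                if "nes_matrix" in state:
                    res2 = meta.nes_vs_hazard(state["nes_matrix"], hr)
                    save("meta", "geneset_r2_vs_hazard.tsv", res2["table"])
            elif stage == "cluster":
                profiles_mat = state["rho_matrix_union"].T  # cancer types x genes
                subsample = 0.8
                m = int(round(subsample * len(profiles_mat)))
                kmax = min(config.cluster_k_max, len(profiles_mat) - 1, m - 1)
                if kmax < 2:
                    raise ValueError("too few cancer types with profiles to cluster")
                res = cluster_mod.consensus_cluster(
                    profiles_mat, k_range=range(2, kmax + 1),
                    reps=config.cluster_reps, subsample=subsample, seed=config.seed,
                )
                if res.assignments is not None:
                    save("cluster", "cluster_assignments.tsv", res.assignments.to_frame())
                save(
                    "cluster", "cluster_delta_area.tsv",
                    pd.DataFrame(
                        {"k": list(res.area), "area": list(res.area.values()),
                         "delta_area": [res.delta_area[k] for k in res.area]}
                    ),
                    index=False,
                )
            elif stage == "pharmaco":
                pdir = Path(config.panel_dir)
                auc_paths = {
                    p.stem.removeprefix("drug_response_"): str(p)
                    for p in sorted(pdir.glob("drug_response_*.csv"))
                }
                prot = pdir / "protein_abundance.csv"
                panel = io.read_cell_line_panel(
                    pdir / "cell_line_expression.csv", pdir / "cell_line_meta.csv",
                    auc_paths or None, prot if prot.exists() else None,
                )
                panel = pharmaco.filter_panel(panel)
                screen = pharmaco.drug_screen(
                    panel, config.query_gene, config.auc_cut,
                    config.pharmaco_min_lines, config.pharmaco_min_each_class,
                )
                save("pharmaco", "drug_screen.tsv", screen, index=False)
                n_types = screen["cancer_type"].nunique()
                compounds, matrix = pharmaco.reportable_compounds(
                    screen, min_types=min(pharmaco.DEFAULT_MIN_TYPES, max(1, n_types // 2))
                )
                save("pharmaco", "reportable_rho_matrix.tsv", matrix)
                if panel.protein is not None:
                    res = pharmaco.mrna_protein_correlation(
                        panel, config.query_gene, list(panel.protein.index)
                    )
                    save(
                        "pharmaco", "mrna_protein.tsv",
                        pd.DataFrame(
                            [{"correlation": res["correlation"], "n": res["n"]}]
                        ),
                        index=False,
                    )
            status[stage] = "ok"
        except Exception as exc:
            logger.exception("stage %s failed", stage)
            status[stage] = f"failed: {exc}"

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "stages": status,
        "outputs": {
            stage: {name: _sha256(out / name) for name in names}
            for stage, names in outputs.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
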