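"""Synthetic multi-cancer cohorts and cell-line panels with planted structure.

The generator emulates the statistical skeleton of a pan-cancer resource:

* several cancer types, each with its own sample size;
* gene *modules* whose members achieve a prescribed Spearman correlation
  with the query gene, optionally switching with a binary TP53-like
  mutation status (Gaussian copula: latent bivariate normals with
  r = 2·sin(π·ρ/6), then a strictly monotone marginal transform onto the
  log10(FPKM + 1) scale — rank correlations survive the transform exactly);
* exponential proportional-hazards survival with log-hazard
  γ·1[query > within-type median] and independent uniform censoring;
* drug AUC values in (0, 1) monotonically linked to query expression
  through the same copula, so the planted Spearman sign and magnitude are
  controlled directly;
* a proteomic channel split over three isoform rows whose sum tracks the
  query mRNA at a prescribed Pearson correlation.

A single integer seed feeds a labelled substream scheme (one independent
generator per cancer type × purpose), so enlarging the gene panel does not
perturb the survival draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datamodel import CellLinePanel, ExpressionMatrix, GeneSetCollection, validate_annotations


def _rng(seed: int, *labels) -> np.random.Generator:
    """Independent generator for a named substream of the global seed."""
    key = zlib.crc32("/".join(map(str, labels)).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def copula_r(rho: float) -> float:
    """Latent normal correlation giving Spearman rho: r = 2 sin(pi rho / 6)."""
    return float(2.0 * np.sin(np.pi * rho / 6.0))


def _per_type(value, cancer_type: str, default=0.0) -> float:
    if isinstance(value, dict):
        return float(value.get(cancer_type, default))
    return float(value)


@dataclass
class ModuleSpec:
    """A gene module with a target Spearman correlation to the query gene.

    ``rho`` applies to all samples of a type; ``rho_wt``/``rho_mut``
    (both given) make the copula parameter switch with mutation status.
    Each may be a scalar or a per-cancer-type dict.
    """

    name: str
    n_genes: int
    rho: float | dict = 0.0
    rho_wt: float | dict | None = None
    rho_mut: float | dict | None = None

    @property
    def stratified(self) -> bool:
        return self.rho_wt is not None or self.rho_mut is not None


@dataclass
class DrugSpec:
    """A compound with a target Spearman correlation between query
    expression and AUC; positive rho = high expression tracks resistance."""

    name: str
    rho: float | dict = 0.0
    location: float = 0.0
    scale: float = 1.5
    source: str = "sanger"


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic pan-cancer cohort + cell-line panel.

    Defaults are a desk-scale rendering of a pan-cancer resource: eight
    tumor types of 150 patients each, a ~1200-gene panel containing a
    positively and a negatively coupled module plus one whose coupling
    flips with mutation status, exponential overall survival on a
    days scale with ~30% censoring, and a small drug panel.
    """

    cancer_types: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("ALPHA", 150), ("BRAVO", 150), ("CHARLIE", 150), ("DELTA", 150),
            ("ECHO", 150), ("FOXTROT", 150), ("GOLF", 150), ("HOTEL", 150),
        ]
    )
    n_genes: int = 1200
    query_gene: str = "MAPT"
    planted_modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec("POSMOD", 60, rho=0.7),
            ModuleSpec("NEGMOD", 40, rho=-0.6),
            ModuleSpec("SWITCHMOD", 40, rho_wt=-0.4, rho_mut=0.4),
            # context-dependent module: couples positively in half the types
            # and negatively in the rest, planting two cancer-type clusters
            ModuleSpec(
                "CONTEXTMOD", 40,
                rho={"ALPHA": 0.6, "BRAVO": 0.6, "CHARLIE": 0.6, "DELTA": 0.6,
                     "ECHO": -0.6, "FOXTROT": -0.6, "GOLF": -0.6, "HOTEL": -0.6},
            ),
        ]
    )
    mut_fraction: float | dict = 0.5
    unknown_fraction: float = 0.0
    survival_gamma: float | dict = field(
        default_factory=lambda: {
            "ALPHA": -1.2, "BRAVO": -0.7, "CHARLIE": 0.0, "DELTA": 0.4,
            "ECHO": 0.8, "FOXTROT": -0.3, "GOLF": 0.2, "HOTEL": 0.6,
        }
    )
    baseline_rate: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.3
    drug_panel: list[DrugSpec] = field(
        default_factory=lambda: [
            DrugSpec("drugA", rho=0.6),
            DrugSpec("drugB", rho=-0.6),
            DrugSpec("drugC", rho=0.0),
        ]
    )
    lines_per_type: int = 25
    n_engineered: int = 3
    n_fibroblast: int = 3
    protein_rho: float = 0.62
    covariate_missing: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for ct, n in self.cancer_types:
            if n < 4:
                raise ValueError(f"cancer type {ct}: n_samples must be >= 4, got {n}")
        for mod in self.planted_modules:
            for val in (mod.rho, mod.rho_wt, mod.rho_mut):
                if val is None:
                    continue
                vals = val.values() if isinstance(val, dict) else [val]
                for v in vals:
                    if not -1.0 < float(v) < 1.0:
                        raise ValueError(
                            f"module {mod.name}: target rho must lie in (-1, 1), got {v}"
                        )
        mf = self.mut_fraction
        for v in (mf.values() if isinstance(mf, dict) else [mf]):
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"mut_fraction must lie in [0, 1], got {v}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError(f"censoring_rate must lie in [0, 1), got {self.censoring_rate}")
        if not -1.0 < self.protein_rho < 1.0:
            raise ValueError("protein_rho must lie in (-1, 1)")

    def module_gene_ids(self) -> dict[str, list[str]]:
        return {
            m.name: [f"{m.name}_{i:03d}" for i in range(m.n_genes)]
            for m in self.planted_modules
        }

    def gene_ids(self) -> list[str]:
        ids = [self.query_gene, "AURKA"]
        for genes in self.module_gene_ids().values():
            ids.extend(genes)
        n_null = self.n_genes - len(ids)
        if n_null < 0:
            raise ValueError(
                f"n_genes={self.n_genes} too small for query+AURKA+modules ({len(ids)})"
            )
        ids.extend(f"NULL{i:05d}" for i in range(n_null))
        return ids


def _marginal_params(spec: SyntheticSpec, gene_ids: list[str]):
    """Per-gene monotone-marginal parameters, independent of sample count."""
    rng = _rng(spec.seed, "marginals")
    a = rng.normal(2.0, 0.5, size=len(gene_ids))
    b = rng.uniform(0.8, 1.2, size=len(gene_ids))
    return a, b


def _to_expression(z: np.ndarray, a, b) -> np.ndarray:
    """Strictly monotone map latent normal -> log10(FPKM + 1) >= 0."""
    return np.log10(np.exp(a + b * z) + 1.0)


def _module_latents(
    mod: ModuleSpec, ct: str, z_q: np.ndarray, is_mut: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(z_q)
    if mod.stratified:
        rho_wt = _per_type(mod.rho_wt if mod.rho_wt is not None else 0.0, ct)
        rho_mut = _per_type(mod.rho_mut if mod.rho_mut is not None else 0.0, ct)
        rho_vec = np.where(is_mut, rho_mut, rho_wt)
    else:
        rho_vec = np.full(n, _per_type(mod.rho, ct))
    r = 2.0 * np.sin(np.pi * rho_vec / 6.0)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError(f"module {mod.name}: infeasible latent correlation (|r| >= 1)")
    eps = rng.standard_normal((mod.n_genes, n))
    return r * z_q + np.sqrt(1.0 - r**2) * eps


def _solve_censor_horizon(hazards: np.ndarray, target: float) -> float:
    """Horizon c of uniform[0, c] censoring hitting an expected censored
    fraction ``target`` for exponential event times with given hazards."""

    def frac(c):
        x = hazards * c
        return float(np.mean((1.0 - np.exp(-x)) / x)) - target

    return brentq(frac, 1e-9, 1e12)


def generate_cohort(spec: SyntheticSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate the clinical cohort: expression matrix + annotation table.

    Reproducible bit-for-bit from ``spec.seed``. Within every cancer type,
    module genes achieve their target Spearman correlation with the query
    gene (per stratum where the module is status-switched); survival follows
    an exponential proportional-hazards model on the median-dichotomized
    query gene.
    """
    gene_ids = spec.gene_ids()
    a, b = _marginal_params(spec, gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    module_ids = spec.module_gene_ids()

    blocks, ann_rows = [], []
    for ct, n in spec.cancer_types:
        rng_lat = _rng(spec.seed, ct, "latent")
        rng_mut = _rng(spec.seed, ct, "mutation")
        rng_surv = _rng(spec.seed, ct, "survival")
        rng_cov = _rng(spec.seed, ct, "covariates")

        mutf = _per_type(spec.mut_fraction, ct)
        is_mut = rng_mut.random(n) < mutf
        trunc = rng_mut.random(n) < 0.5  # MUT split into the two classes
        unknown = rng_mut.random(n) < spec.unknown_fraction

        z = np.empty((len(gene_ids), n))
        z_q = rng_lat.standard_normal(n)
        z[gene_pos[spec.query_gene]] = z_q
        for mod in spec.planted_modules:
            rows = [gene_pos[g] for g in module_ids[mod.name]]
            z[rows] = _module_latents(mod, ct, z_q, is_mut, rng_lat)
        null_rows = [
            gene_pos[g] for g in gene_ids
            if g != spec.query_gene and not any(g in ids for ids in module_ids.values())
        ]
        z[null_rows] = rng_lat.standard_normal((len(null_rows), n))

        expr = _to_expression(z, a[:, None], b[:, None])
        sample_ids = [f"{ct}-{i:04d}" for i in range(n)]
        blocks.append(pd.DataFrame(expr, index=gene_ids, columns=sample_ids))

        # survival: exponential PH on the within-type median split
        q_expr = expr[gene_pos[spec.query_gene]]
        high = q_expr > np.median(q_expr)
        gamma = _per_type(spec.survival_gamma, ct)
        haz = spec.baseline_rate * np.exp(gamma * high)
        t_event = rng_surv.exponential(1.0 / haz)
        if spec.censoring_rate > 0:
            horizon = _solve_censor_horizon(haz, spec.censoring_rate)
            t_cens = rng_surv.uniform(0.0, horizon, size=n)
        else:
            t_cens = np.full(n, np.inf)
        os_time = np.minimum(t_event, t_cens)
        os_event = t_event <= t_cens

        size_stage = rng_cov.choice([1, 2, 3, 4], size=n, p=[0.3, 0.4, 0.2, 0.1]).astype(float)
        node_stage = rng_cov.choice([0, 1, 2, 3], size=n, p=[0.5, 0.25, 0.15, 0.1]).astype(float)
        met_stage = rng_cov.choice([0, 1], size=n, p=[0.85, 0.15]).astype(float)
        for col in (size_stage, node_stage, met_stage):
            col[rng_cov.random(n) < spec.covariate_missing] = np.nan

        status = np.where(is_mut, "MUT", "WT")
        klass = np.where(is_mut, np.where(trunc, "TruncatingHomDel", "InframeMissense"), "WT")
        status = np.where(unknown, None, status)
        klass = np.where(unknown, "Unknown", klass)

        aurka = expr[gene_pos["AURKA"]]
        for i in range(n):
            ann_rows.append(
                {
                    "sample_id": sample_ids[i],
                    "cancer_type": ct,
                    "tp53_status": status[i],
                    "tp53_class": klass[i],
                    "os_time": float(os_time[i]),
                    "os_event": bool(os_event[i]),
                    "size_stage": size_stage[i],
                    "node_stage": node_stage[i],
                    "met_stage": met_stage[i],
                    "aurka": float(aurka[i]),
                }
            )

    matrix = ExpressionMatrix(pd.concat(blocks, axis=1))
    ann = validate_annotations(pd.DataFrame(ann_rows))
    return matrix, ann


def generate_genesets(
    spec: SyntheticSpec,
    requests: list[tuple[str, str, int]] | None = None,
) -> GeneSetCollection:
    """Emit planted-positive / planted-negative / size-matched null genesets.

    ``requests`` is a list of (name, kind, size) with kind in
    {"positive", "negative", "null"}; positive/negative sets are drawn from
    the correspondingly signed planted modules, null sets from the
    background genes. Defaults to one set of each kind, size 50 (capped at
    module size).
    """
    module_ids = spec.module_gene_ids()
    pos_pool, neg_pool = [], []
    for mod in spec.planted_modules:
        if mod.stratified:
            continue
        rho_vals = mod.rho.values() if isinstance(mod.rho, dict) else [mod.rho]
        mean_rho = float(np.mean(list(rho_vals)))
        if mean_rho > 0:
            pos_pool.extend(module_ids[mod.name])
        elif mean_rho < 0:
            neg_pool.extend(module_ids[mod.name])
    null_pool = [g for g in spec.gene_ids() if g.startswith("NULL")]
    pools = {"positive": pos_pool, "negative": neg_pool, "null": null_pool}

    if requests is None:
        requests = [
            ("PLANTED_POSITIVE", "positive", min(50, len(pos_pool))),
            ("PLANTED_NEGATIVE", "negative", min(50, len(neg_pool))),
            ("NULL_SET", "null", 50),
        ]
    rng = _rng(spec.seed, "genesets")
    coll = GeneSetCollection()
    for name, kind, size in requests:
        if kind not in pools:
            raise ValueError(f"unknown geneset kind {kind!r}")
        pool = pools[kind]
        if size > len(pool):
            raise ValueError(
                f"requested set {name!r} of size {size} exceeds available "
                f"{kind} pool ({len(pool)} genes)"
            )
        genes = rng.choice(pool, size=size, replace=False)
        coll.add(name, genes, provenance=f"synthetic_{kind}")
    return coll


def generate_cell_line_panel(spec: SyntheticSpec) -> CellLinePanel:
    """Generate the pre-clinical panel: expression, metadata, drug AUC in
    (0, 1) monotonically tied to query expression, and a three-isoform
    protein channel whose sum hits ``spec.protein_rho`` with the mRNA."""
    gene_ids = spec.gene_ids()
    a, b = _marginal_params(spec, gene_ids)
    q_idx = gene_ids.index(spec.query_gene)

    blocks, meta_rows = [], []
    zq_all, line_types, line_ids = [], [], []
    for ct, _ in spec.cancer_types:
        rng = _rng(spec.seed, ct, "lines")
        n = spec.lines_per_type
        z = rng.standard_normal((len(gene_ids), n))
        ids = [f"{ct}-CL{i:03d}" for i in range(n)]
        blocks.append(pd.DataFrame(_to_expression(z, a[:, None], b[:, None]),
                                   index=gene_ids, columns=ids))
        zq_all.append(z[q_idx])
        line_ids.extend(ids)
        line_types.extend([ct] * n)
        meta_rows.extend(
            {"cell_line": i, "cancer_type": ct, "lineage": "tumour"} for i in ids
        )

    rng_decoy = _rng(spec.seed, "decoys")
    for label, count in (("Engineered", spec.n_engineered), ("Fibroblast", spec.n_fibroblast)):
        z = rng_decoy.standard_normal((len(gene_ids), count))
        ids = [f"{label.upper()}-{i:03d}" for i in range(count)]
        blocks.append(pd.DataFrame(_to_expression(z, a[:, None], b[:, None]),
                                   index=gene_ids, columns=ids))
        line_ids.extend(ids)
        line_types.extend([label] * count)
        meta_rows.extend(
            {"cell_line": i, "cancer_type": label, "lineage": label} for i in ids
        )

    expr = ExpressionMatrix(pd.concat(blocks, axis=1))
    meta = pd.DataFrame(meta_rows)
    zq = np.concatenate(zq_all)  # tumour lines only, in column order

    # drug AUC through the same copula: monotone in the latent, so the
    # planted Spearman with query expression is exact in distribution
    auc = pd.DataFrame(index=line_ids, columns=[], dtype=float)
    auc_source: dict[str, str] = {}
    rng_drug = _rng(spec.seed, "drugs")
    n_tum = len(zq)
    for drug in spec.drug_panel:
        col = np.full(len(line_ids), np.nan)
        vals = np.empty(n_tum)
        offset = 0
        for (ct, _), z_block in zip(spec.cancer_types, zq_all):
            m = len(z_block)
            r = copula_r(_per_type(drug.rho, ct))
            u = r * z_block + np.sqrt(1.0 - r**2) * rng_drug.standard_normal(m)
            vals[offset : offset + m] = expit(drug.location + drug.scale * u)
            offset += m
        col[:n_tum] = vals
        key = f"{drug.source}:{drug.name}"
        auc[key] = col
        auc_source[key] = drug.source

    # protein: sum of three isoform channels tracks query mRNA at protein_rho
    rng_prot = _rng(spec.seed, "protein")
    q_expr = expr.values.iloc[q_idx].to_numpy()
    e = (q_expr - q_expr.mean()) / q_expr.std()
    noise = rng_prot.standard_normal(len(e))
    signal = spec.protein_rho * e + np.sqrt(1.0 - spec.protein_rho**2) * noise
    d1 = rng_prot.normal(0.0, 0.05, size=len(e))
    d2 = rng_prot.normal(0.0, 0.05, size=len(e))
    protein = pd.DataFrame(
        {
            "TAU_ISO1": signal / 3.0 + d1,
            "TAU_ISO2": signal / 3.0 + d2,
            "TAU_ISO3": signal / 3.0 - d1 - d2,
        },
        index=expr.sample_ids,
    ).T

    return CellLinePanel(
        expression=expr, meta=meta, auc=auc, auc_source=auc_source, protein=protein
    )
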