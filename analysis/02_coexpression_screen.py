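#!/usr/bin/env python
"""Per-cancer-type co-expression screen of the query gene.

Filters to expressed genes (mean > 0.5 and SD > 0.2 in at least one
cancer type), profiles Spearman correlation of every gene against the
query within each type, and reports the |rho| > 0.6 screen: per-type
counts, the pan-cancer union, and the gene-by-type rho matrix used later
for clustering.
"""

from pathlib import Path

import pandas as pd

from pancontext import coexpression, io

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "coexpression"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression_matrix(DATA / "expression.tsv")
    ann = io.read_annotations(DATA / "clinical.csv")
    groups = ann.set_index("sample_id")["cancer_type"]

    kept = coexpression.filter_genes(expr, groups, query_gene="MAPT")
    print(f"expressed-gene filter: {len(kept)} of {expr.shape[0]} genes retained")
    fexpr = expr.subset_genes(kept)

    profiles = coexpression.profile_contexts(fexpr, ann, "MAPT")
    counts = []
    for prof in profiles:
        prof.table.to_csv(OUT / f"profile_{prof.cancer_type}.tsv", sep="\t")
        pos, neg = coexpression.significant_genes(prof)
        counts.append({"cancer_type": prof.cancer_type, "positive": len(pos),
                       "negative": len(neg), "total": len(pos) + len(neg)})
    counts = pd.DataFrame(counts).set_index("cancer_type")
    counts.to_csv(OUT / "significant_counts.tsv", sep="\t")
    print(counts)

    union, rho_matrix = coexpression.union_correlated_genes(profiles)
    rho_matrix.to_csv(OUT / "union_rho_matrix.tsv", sep="\t")
    print(f"{len(union)} genes pass |rho| > 0.6 in at least one cancer type")

    mean_level = pd.Series(
        {p.cancer_type: float(fexpr.gene("MAPT")[
            ann.loc[ann.cancer_type == p.cancer_type, "sample_id"]].mean())
         for p in profiles}
    )
    link = coexpression.counts_vs_level(counts, mean_level)
    print("correlation of per-type hit counts with mean query expression:",
          {k: None if v != v else round(v, 3) for k, v in link.items()})


if __name__ == "__main__":
    main()
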