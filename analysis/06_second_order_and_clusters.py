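#!/usr/bin/env python
"""Second-order analyses across cancer types.

(1) For every gene, correlate its per-type association with the query
gene against the per-type univariate hazard ratios — genes whose
coupling tracks the prognostic effect. (2) Consensus-cluster the cancer
types by their correlation profiles (subsampled K-means, delta-area /
PAC k selection).
"""

from pathlib import Path

import pandas as pd

from pancontext import cluster, meta

ROOT = Path(__file__).resolve().parent.parent
COEX = ROOT / "results" / "coexpression"
SURV = ROOT / "results" / "survival"
OUT = ROOT / "results" / "meta"

SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rho_cols = {}
    for path in sorted(COEX.glob("profile_*.tsv")):
        ct = path.stem.removeprefix("profile_")
        rho_cols[ct] = pd.read_csv(path, sep="\t", index_col=0)["rho"]
    rho_matrix = pd.DataFrame(rho_cols)

    grid = pd.read_csv(SURV / "survival_grid.tsv", sep="\t")
    uni = grid[(grid.stratum == "ALL") & (grid.model == "univariate")]
    hr = uni.set_index("cancer_type")["hr"].dropna()

    res = meta.correlation_vs_hazard(rho_matrix, hr)
    tbl = res["table"]
    tbl.to_csv(OUT / "gene_r2_vs_hazard.tsv", sep="\t")
    print(f"genes with |r2| > 0.5 between rho profile and HR profile: "
          f"{res['n_above']} positive, {res['n_below']} negative "
          f"(of {len(tbl)}; with only 8 contexts, individual extremes are "
          f"expected by chance)")
    for mod in ("CONTEXTMOD", "POSMOD", "NEGMOD", "NULL"):
        sel = tbl[tbl.index.str.startswith(mod)]
        print(f"  median r2, {mod} genes: {sel['r2'].median():+.2f}")
    print("  (the context-dependent module couples where survival is good, "
          "so its r2 sits systematically below zero)")

    union_rho = pd.read_csv(COEX / "union_rho_matrix.tsv", sep="\t", index_col=0)
    profiles = union_rho.T  # cancer types x genes
    # with 8 items and 6-item subsamples, k beyond 4 would run out of
    # headroom for stability to discriminate
    cres = cluster.consensus_cluster(
        profiles, k_range=range(2, 5), reps=200, subsample=0.75, seed=SEED
    )
    pd.DataFrame({"k": list(cres.area), "area": list(cres.area.values()),
                  "delta_area": [cres.delta_area[k] for k in cres.area],
                  "pac": [cres.pac[k] for k in cres.area]}
                 ).to_csv(OUT / "cluster_selection.tsv", sep="\t", index=False)
    print(f"\nconsensus clustering of cancer types: chosen k = {cres.chosen_k}")
    if cres.assignments is not None:
        cres.assignments.to_frame().to_csv(OUT / "cluster_assignments.tsv", sep="\t")
        for lab, members in cres.assignments.groupby(cres.assignments):
            print(f"  cluster {lab}: {list(members.index)}")


if __name__ == "__main__":
    main()
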