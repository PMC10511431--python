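#!/usr/bin/env python
"""Pre-ranked geneset enrichment on the correlation-ranked gene lists.

For each cancer type, genes are ranked by their correlation with the
query gene and tested against the geneset collection (planted positive /
negative modules plus a size-matched null set). Reports NES per context
and the strict pan-cancer reporting rule (FDR < 0.1% and |NES| > 2.3 in
at least one cancer type).
"""

from pathlib import Path

import pandas as pd

from pancontext import gsea, io

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
COEX = ROOT / "results" / "coexpression"
OUT = ROOT / "results" / "gsea"

SEED = 0
N_PERM = 500


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    collection = io.read_gmt(DATA / "genesets.gmt")
    results = {}
    for path in sorted(COEX.glob("profile_*.tsv")):
        ct = path.stem.removeprefix("profile_")
        tbl = pd.read_csv(path, sep="\t", index_col=0)
        ranked = tbl["rho"].dropna().sort_values(ascending=False)
        res = gsea.normalized_enrichment(
            ranked, collection, n_perm=N_PERM, seed=SEED, context=ct
        )
        res.to_csv(OUT / f"gsea_{ct}.tsv", sep="\t")
        results[ct] = res
    nes = pd.DataFrame({ct: r["nes"] for ct, r in results.items()})
    nes.to_csv(OUT / "nes_matrix.tsv", sep="\t")
    print("NES per geneset and cancer type:")
    print(nes.round(2))
    reported = gsea.significant_genesets(results)
    reported.to_csv(OUT / "reported.tsv", sep="\t", index=False)
    print(f"\ngenesets passing FDR<0.001 & |NES|>2.3 in >=1 type: "
          f"{sorted(reported['geneset'].unique())}")


if __name__ == "__main__":
    main()
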