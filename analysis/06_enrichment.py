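"""Dual-ranked preranked enrichment (signal2noise and consensus-model
loadings, per cell type and layer), significance filtering across layers,
Wang-similarity clustering of retained terms, and over-representation of
the selected features in each gene set.
"""
import json

import pandas as pd

from common import RESULTS, get_pipeline


def main() -> None:
    pipe = get_pipeline()
    pipe.run(stages=["enrich"])
    retained = pd.read_csv(RESULTS / "terms_retained.tsv", sep="\t", index_col="set_id")
    truth = json.load(open(RESULTS / "truth.json"))
    planted = set(truth["enriched_sets"])
    print(
        f"retained {len(retained)} terms (p<0.05 and q<0.1 in both layers of "
        f">=1 cell type), in {retained['cluster'].nunique()} similarity clusters"
    )
    print(f"planted sets recovered among retained: "
          f"{sorted(planted & set(retained.index))} of {sorted(planted)}")
    ora = pd.read_csv(RESULTS / "ora_selected.tsv", sep="\t")
    top = ora.nsmallest(3, "p")
    print("strongest over-representation of selected features:")
    for _, row in top.iterrows():
        print(f"  {row.set_id}: p={row.p:.2e}, fold={row.fold:.1f}, overlap={row.overlap}")


if __name__ == "__main__":
    main()
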