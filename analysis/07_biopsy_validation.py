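"""Validate the cell-model findings in the synthetic biopsy cohort:
average-Z pathway scores of the core-enrichment genes compared across
disease stages (one-way ANOVA), SAM differential expression of advanced
disease vs donors, and Spearman correlation with phenotypes.
"""
import json

import pandas as pd

from common import RESULTS, get_pipeline


def main() -> None:
    pipe = get_pipeline()
    pipe.run(stages=["validate"])
    scores = pd.read_csv(RESULTS / "pathway_scores.tsv", sep="\t", index_col=0)
    means = scores.groupby("group")["z_avg"].mean()
    anova = json.load(open(RESULTS / "pathway_anova.json"))
    print("mean pathway Z-score by group:")
    for g in ("LD", "early_DKD", "advanced_DKD"):
        print(f"  {g}: {means[g]:+.3f}")
    print(f"one-way ANOVA: F={anova['F']:.1f}, p={anova['p']:.2e}")
    sam = pd.read_csv(RESULTS / "sam_advanced_vs_ld.tsv", sep="\t", index_col="gene")
    print(f"SAM advanced vs donors: {(sam['q'] < 0.05).sum()} genes at q<0.05")
    spear = pd.read_csv(RESULTS / "spearman_phenotypes.tsv", sep="\t")
    gfr = spear[spear["phenotype"] == "GFR"].nsmallest(3, "p")
    for _, row in gfr.iterrows():
        print(f"  {row.gene} vs GFR: rho={row.rho:+.2f}, p={row.p:.2e}")


if __name__ == "__main__":
    main()
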