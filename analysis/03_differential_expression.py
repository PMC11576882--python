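"""Per-cell-type moderated differential expression (insulin-resistant vs
basal) with a global Benjamini-Hochberg correction across the four cell
types, transcript-protein fold-change correlation, and cell-line-specific
feature calling.
"""
import json

import pandas as pd

from common import RESULTS, get_pipeline


def main() -> None:
    pipe = get_pipeline()
    pipe.run(stages=["de"])
    for layer in ("rna", "protein"):
        de = pd.read_csv(RESULTS / f"de_{layer}.tsv", sep="\t")
        counts = de[de["fdr"] < 0.05].groupby("cell_type").size()
        print(f"{layer}: DE features at FDR<0.05 per cell type:")
        print("  " + ", ".join(f"{ct}={n}" for ct, n in counts.items()))
    corr = pd.read_csv(RESULTS / "fc_correlation.tsv", sep="\t")
    rng = corr["r"]
    print(
        f"transcript-protein log2FC Pearson r: {rng.min():.3f}-{rng.max():.3f} "
        "across cell types"
    )
    spec = json.load(open(RESULTS / "cell_specific_rna.json"))
    n_spec = {ct: len(v["up"]) + len(v["down"]) for ct, v in spec.items()}
    print(f"cell-line-specific RNA calls: {n_spec}")


if __name__ == "__main__":
    main()
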