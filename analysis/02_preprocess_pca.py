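"""Filter and normalise both omics layers (cpm filter + TMM + log2-cpm for
RNA; log2 + median centring for protein) and compute the PCA sample
overview: samples should cluster primarily by cell type.
"""
import pandas as pd

from common import RESULTS, get_pipeline


def main() -> None:
    pipe = get_pipeline()
    pipe.run(stages=["preprocess"])
    for layer in ("rna", "protein"):
        pca = pd.read_csv(RESULTS / f"pca_{layer}.tsv", sep="\t", index_col=0)
        ve1 = pca["variance_explained_PC1"].iloc[0]
        cell_type = pca.index.str.split("_").str[0]
        within = pca.groupby(cell_type)["PC1"].std().mean()
        between = pca.groupby(cell_type)["PC1"].mean().std()
        print(
            f"{layer}: PC1 explains {ve1:.1%} of variance; "
            f"between/within cell-type spread on PC1 = {between / within:.1f}x"
        )


if __name__ == "__main__":
    main()
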