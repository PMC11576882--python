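"""Shared configuration for the numbered analysis drivers.

Every driver operates on the same output directory (results/analysis) with
the same seed, so later steps resume from the files earlier steps wrote.
"""
from pathlib import Path

from iromics.pipeline import Pipeline, PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def get_pipeline(seed: int = 1) -> Pipeline:
    cfg = PipelineConfig(
        outdir=str(RESULTS),
        seed=seed,
        n_perm=199,          # consensus-model permutations (desk scale)
        gsea_n_perm=500,
        sam_n_perm=200,
    )
    return Pipeline(cfg)
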