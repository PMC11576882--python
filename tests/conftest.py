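import numpy as np
import pandas as pd
import pytest

from iromics.datatypes import NormalizedMatrix, OmicsMatrix, SampleMeta
from iromics.sim import SimConfig, simulate_paired_omics


def make_samples(n_per_cond: int = 5, cell_type: str = "Pod") -> list[SampleMeta]:
    metas = []
    for cond in ("basal", "insulin_resistant"):
        for rep in range(1, n_per_cond + 1):
            metas.append(
                SampleMeta(
                    sample_id=f"{cell_type}_{cond}_{rep}",
                    cell_type=cell_type,
                    condition=cond,
                    replicate=rep,
                )
            )
    return metas


def make_counts(values: np.ndarray, n_per_cond: int = 5) -> OmicsMatrix:
    metas = make_samples(n_per_cond)
    genes = [f"g{i:03d}" for i in range(values.shape[0])]
    return OmicsMatrix(
        pd.DataFrame(values, index=genes, columns=[m.sample_id for m in metas]),
        metas,
        "rna",
    )


def make_normalized(values: np.ndarray, n_per_cond: int = 5, layer: str = "rna") -> NormalizedMatrix:
    metas = make_samples(n_per_cond)
    genes = [f"g{i:03d}" for i in range(values.shape[0])]
    ids = [m.sample_id for m in metas]
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=genes, columns=ids),
        norm_factors=pd.Series(1.0, index=ids),
        samples=metas,
        layer=layer,
    )


@pytest.fixture(scope="session")
def default_paired():
    """One paired dataset at the default study design (seed 1)."""
    return simulate_paired_omics(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_paired():
    """A reduced paired dataset for fast end-to-end checks."""
    cfg = SimConfig(
        n_genes=400, n_shared_signal=20, n_specific_signal=10, n_cell_types=2, seed=7
    )
    return simulate_paired_omics(cfg)
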