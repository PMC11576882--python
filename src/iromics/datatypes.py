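"""Core containers shared by every stage of the pipeline.

An :class:`OmicsMatrix` carries one omics layer (RNA counts or protein
intensities) as a feature-by-sample table plus per-column sample metadata;
it is the unit consumed by normalisation, differential expression and the
multiblock model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("basal", "insulin_resistant")
LAYERS = ("rna", "protein")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample column."""

    sample_id: str
    cell_type: str
    condition: str
    replicate: int
    batch: str = "A"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


def samples_to_frame(samples: Sequence[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "cell_type": [s.cell_type for s in samples],
            "condition": [s.condition for s in samples],
            "replicate": [s.replicate for s in samples],
            "batch": [s.batch for s in samples],
        }
    ).set_index("sample_id")


@dataclass
class OmicsMatrix:
    """One omics layer: feature-by-sample values plus sample metadata.

    RNA layers hold non-negative integer counts; protein layers hold strictly
    positive intensities.
    """

    values: pd.DataFrame  # features x samples
    samples: list[SampleMeta]
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if len(self.samples) != self.values.shape[1]:
            raise ValueError("one SampleMeta required per value column")
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("sample metadata order must match value columns")
        if not self.values.index.is_unique:
            raise ValueError("feature_ids must be unique")
        keys = {(s.cell_type, s.condition, s.replicate) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("(cell_type, condition, replicate) must be unique")
        arr = self.values.to_numpy()
        if self.layer == "rna":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("RNA counts must be non-negative integers")
        else:
            if (arr <= 0).any():
                raise ValueError("protein intensities must be strictly positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_labels(self) -> np.ndarray:
        return np.array([s.condition for s in self.samples])

    def subset_features(self, mask: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[np.asarray(mask, bool)], self.samples, self.layer)

    def subset_samples(self, keep: Sequence[str]) -> "OmicsMatrix":
        keep = list(keep)
        smap = {s.sample_id: s for s in self.samples}
        return OmicsMatrix(self.values[keep], [smap[k] for k in keep], self.layer)


@dataclass
class NormalizedMatrix:
    """log2-scale feature-by-sample matrix after filtering and normalisation."""

    values: pd.DataFrame
    norm_factors: pd.Series  # per sample, geometric mean 1
    samples: list[SampleMeta]
    layer: str

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def condition_labels(self) -> np.ndarray:
        return np.array([s.condition for s in self.samples])


@dataclass
class PcaSummary:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray


@dataclass
class DEResult:
    """Per-feature moderated differential-expression statistics for one
    cell type x layer contrast (insulin_resistant minus basal)."""

    table: pd.DataFrame  # columns: log2fc, t, p, fdr (fdr filled later)
    cell_type: str
    layer: str
    residual_df: float
    prior_df: float
    prior_var: float


@dataclass
class CorrelationResult:
    r: float
    n_features: int
    cell_type: str


@dataclass
class SimTruth:
    """Ground truth of every planted effect, enabling recovery scoring."""

    shared_genes: set[str]
    specific_genes: dict[str, set[str]]
    planted_log2fc: dict[tuple[str, str, str], float]  # (gene, cell_type, layer)
    enriched_sets: set[str] = field(default_factory=set)
    biopsy_shifted_genes: set[str] = field(default_factory=set)

    def signal_genes(self) -> set[str]:
        out = set(self.shared_genes)
        for g in self.specific_genes.values():
            out |= g
        return out

    def planted_effect(self, gene: str, cell_type: str, layer: str) -> float:
        """Planted log2 fold change; 0 for every non-signal combination."""
        return self.planted_log2fc.get((gene, cell_type, layer), 0.0)

    def effect_pairs(self) -> np.ndarray:
        """Unique (RNA, protein) planted-effect draws, one row per draw."""
        seen: dict[tuple[str, str], list[float]] = {}
        for (gene, ct, layer), eff in self.planted_log2fc.items():
            ct_key = "shared" if gene in self.shared_genes else ct
            pair = seen.setdefault((gene, ct_key), [np.nan, np.nan])
            pair[0 if layer == "rna" else 1] = eff
        rows = [seen[k] for k in sorted(seen)]
        return np.array(rows, dtype=float).reshape(-1, 2)


@dataclass
class BiopsyCohort:
    """Log-scale biopsy-style expression with group labels and phenotypes."""

    expression: pd.DataFrame  # genes x samples, log2 scale
    groups: pd.Series  # per sample: LD / early_DKD / advanced_DKD
    phenotypes: pd.DataFrame  # samples x phenotype columns

    def __post_init__(self) -> None:
        if not self.groups.index.equals(self.expression.columns):
            raise ValueError("groups must be indexed by the expression columns")
        if not self.phenotypes.index.equals(self.expression.columns):
            raise ValueError("phenotypes must be row-aligned to samples")
        if (self.groups.value_counts() < 3).any():
            raise ValueError("each group needs at least 3 samples")
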