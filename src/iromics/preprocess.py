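"""Expression filtering, normalisation, transformation, scaling and the PCA
sample overview.

RNA counts are filtered (cpm > 1 in at least one library), normalised with
trimmed-mean-of-M-values (TMM) factors and transformed to log2 counts per
million with a prior count; protein intensities are log2-transformed and
median-centred per sample before following the same downstream path.
Filtering precedes factor computation.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import NormalizedMatrix, OmicsMatrix, PcaSummary

logger = logging.getLogger("iromics.preprocess")


def filter_low_expression(counts: OmicsMatrix) -> np.ndarray:
    """Mask of features with cpm strictly greater than 1 in >=1 library.

    RNA-specific: the cpm rule has no meaning for intensity data.
    """
    if counts.layer != "rna":
        raise ValueError("low-expression cpm filter applies to the RNA layer only")
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    cpm = arr / lib * 1e6
    return (cpm > 1.0).any(axis=1)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f).

    Trims 30% of M-values on each side and 5% of A-values, then takes the
    inverse-variance weighted mean of the surviving M-values (weights from the
    asymptotic binomial variance of a log count ratio).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        log_r = np.log2(p_obs / p_ref)
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: OmicsMatrix, ref_sample: str | None = None) -> pd.Series:
    """Per-sample TMM normalisation factors, re-centred to geometric mean 1.

    The reference defaults to the sample whose upper-quartile cpm is closest
    to the mean upper quartile.
    """
    arr = counts.values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise ValueError(f"all-zero samples: {bad}")
    if ref_sample is None:
        uq = np.array([np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.sample_ids.index(ref_sample)
    ref = arr[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair(arr[:, j], ref, lib[j], lib[ref_idx])
            for j in range(arr.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="norm_factor")


def log_cpm_transform(
    counts: OmicsMatrix, factors: pd.Series, prior_count: float = 0.5
) -> NormalizedMatrix:
    """log2 counts-per-million with a prior count and effective library sizes.

    value = log2((count + prior) / (lib*factor + 2*prior) * 1e6)
    """
    arr = counts.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    lib = arr.sum(axis=0) * factors.reindex(counts.sample_ids).to_numpy()
    vals = np.log2((arr + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=counts.feature_ids, columns=counts.sample_ids),
        norm_factors=factors,
        samples=counts.samples,
        layer=counts.layer,
    )


def normalize_rna(counts: OmicsMatrix, prior_count: float = 0.5) -> NormalizedMatrix:
    """Filter (cpm > 1 in >=1 library), TMM-normalise, log2-cpm transform."""
    kept = counts.subset_features(filter_low_expression(counts))
    return log_cpm_transform(kept, tmm_factors(kept), prior_count)


def normalize_protein(protein: OmicsMatrix) -> NormalizedMatrix:
    """log2 intensities, median-centred per sample.

    TMM's count model does not apply to intensities; per-sample median
    centring (preserving the grand median) plays the equivalent role before
    the shared downstream differential-expression path.
    """
    if protein.layer != "protein":
        raise ValueError("expected a protein layer")
    logv = np.log2(protein.values.to_numpy(dtype=float))
    med = np.median(logv, axis=0)
    vals = logv - med + med.mean()
    factors = np.exp2(med - med.mean())
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=protein.feature_ids, columns=protein.sample_ids),
        norm_factors=pd.Series(factors, index=protein.sample_ids, name="norm_factor"),
        samples=protein.samples,
        layer=protein.layer,
    )


def autoscale(
    matrix: NormalizedMatrix | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centre each feature to mean 0 and scale to unit sd (ddof=1).

    Zero-variance features are dropped (logged, not fatal). Returns the scaled
    feature-by-sample table and a (mean, sd) table usable to re-apply the
    transform.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("autoscale: dropping %d zero-variance features", int((~keep).sum()))
    scaled = (arr[keep] - mean[keep, None]) / sd[keep, None]
    idx = values.index[keep]
    stats = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]}, index=idx)
    return pd.DataFrame(scaled, index=idx, columns=values.columns), stats


def pca_overview(matrix: NormalizedMatrix | pd.DataFrame, n_components: int = 2) -> PcaSummary:
    """Sample scores on the leading principal components of centred data."""
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    x = values.to_numpy(dtype=float).T  # samples x features
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    var_exp = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    return PcaSummary(
        scores=pd.DataFrame(
            scores,
            index=values.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        variance_explained=var_exp,
    )
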