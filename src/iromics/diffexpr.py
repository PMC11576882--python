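"""Moderated differential expression per cell type, global multiple-testing
correction across cell types, transcript-protein fold-change correlation and
cell-line-specific feature calling.

The moderated t shrinks per-feature sample variances toward a common prior:
with residual variance s^2 on d degrees of freedom and a prior (d0, s0^2)
estimated by method-of-moments on log sample variances,

    s_post^2 = (d0*s0^2 + d*s^2) / (d0 + d),
    t_mod    = log2fc / (s_post * sqrt(v)),   df = d0 + d,

where v is the contrast's unscaled variance from the design matrix.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .datatypes import CorrelationResult, DEResult, NormalizedMatrix

logger = logging.getLogger("iromics.diffexpr")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < tol:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from log sample variances.

    Models s^2 ~ s0^2 * chi^2_d / d scaled by an F-like prior; the moments of
    log(s^2) give closed-form estimates via digamma/trigamma.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if (~ok).any():
        logger.info("estimate_prior: excluding %d zero variances", int((~ok).sum()))
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def _design(matrix: NormalizedMatrix, include_batch: bool) -> tuple[np.ndarray, np.ndarray]:
    cond = np.array([1.0 if s.condition == "insulin_resistant" else 0.0 for s in matrix.samples])
    cols = [np.ones_like(cond), cond]
    if include_batch:
        batches = sorted({s.batch for s in matrix.samples})
        for b in batches[1:]:
            cols.append(np.array([1.0 if s.batch == b else 0.0 for s in matrix.samples]))
    design = np.column_stack(cols)
    contrast = np.zeros(design.shape[1])
    contrast[1] = 1.0  # insulin_resistant minus basal
    return design, contrast


def fit_moderated_de(
    matrix: NormalizedMatrix,
    cell_type: str | None = None,
    include_batch: bool = False,
    prior_df: float | str = "auto",
) -> DEResult:
    """Per-feature moderated-t contrast (insulin_resistant minus basal).

    ``prior_df`` overrides the estimated d0: 0 gives the ordinary two-sample
    t, ``inf`` full shrinkage to the common prior variance.
    """
    conds = matrix.condition_labels()
    for c in ("basal", "insulin_resistant"):
        if (conds == c).sum() < 2:
            raise ValueError(f"need >=2 replicates in condition {c!r}")
    design, contrast = _design(matrix, include_batch)
    n, k = design.shape
    rank = np.linalg.matrix_rank(design)
    d = n - rank
    if d <= 0:
        raise ValueError("zero residual degrees of freedom")
    y = matrix.values.to_numpy(dtype=float)  # features x samples
    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T  # features x k
    resid = y - beta @ design.T
    s2 = (resid ** 2).sum(axis=1) / d
    xtx_inv = np.linalg.pinv(design.T @ design)
    v = float(contrast @ xtx_inv @ contrast)
    log2fc = beta @ contrast

    if prior_df == "auto":
        d0, s0_2 = estimate_prior(s2, d)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / np.sqrt(s2_post * v)
    p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {"log2fc": log2fc, "t": t_mod, "p": p, "fdr": fdr},
        index=matrix.feature_ids,
    )
    ct = cell_type or (matrix.samples[0].cell_type if matrix.samples else "NA")
    return DEResult(
        table=table,
        cell_type=ct,
        layer=matrix.layer,
        residual_df=float(d),
        prior_df=float(d0) if not np.isinf(d0) else np.inf,
        prior_var=s0_2,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN inputs stay NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if (~ok).any():
        logger.info("bh_adjust: excluding %d NaN p-values", int((~ok).sum()))
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def global_bh_adjust(results: list[DEResult]) -> list[DEResult]:
    """Pool nominal p-values across cell types (one layer) and re-adjust.

    Adjusted values are written back into each result's ``fdr`` column.
    """
    layers = {r.layer for r in results}
    if len(layers) != 1:
        raise ValueError("global adjustment pools one layer at a time")
    pooled = np.concatenate([r.table["p"].to_numpy() for r in results])
    fdr = bh_adjust(pooled)
    pos = 0
    for r in results:
        m = len(r.table)
        r.table["fdr"] = fdr[pos: pos + m]
        pos += m
    return results


def fc_correlation(de_rna: DEResult, de_protein: DEResult) -> CorrelationResult:
    """Pearson correlation of RNA vs protein log2 fold changes on the
    feature intersection."""
    common = de_rna.table.index.intersection(de_protein.table.index)
    if len(common) == 0:
        raise ValueError("no shared features between layers")
    a = de_rna.table.loc[common, "log2fc"].to_numpy()
    b = de_protein.table.loc[common, "log2fc"].to_numpy()
    r = float(np.corrcoef(a, b)[0, 1])
    return CorrelationResult(r=r, n_features=len(common), cell_type=de_rna.cell_type)


def cell_specific_features(
    de_by_cell_type: dict[str, DEResult],
    p_thr: float = 0.05,
    fc_band: float = 0.1,
    fdr_thr: float = 0.1,
) -> dict[str, dict[str, set[str]]]:
    """Cell-line-specific up/down calls within one omics layer.

    A feature is specific-up in cell type C iff it is significantly up there
    (fdr < fdr_thr, log2fc > 0) while in every other cell type where it was
    measured p > p_thr and log2fc < fc_band (mirrored for down).  Features not
    measured in another cell type trivially satisfy that cell type's
    constraint (cell-line-restricted expression).
    """
    if len(de_by_cell_type) < 2:
        raise ValueError("need at least two cell types")
    out: dict[str, dict[str, set[str]]] = {}
    for ct, res in de_by_cell_type.items():
        others = [o for o in de_by_cell_type if o != ct]
        up: set[str] = set()
        down: set[str] = set()
        tab = res.table
        sig_up = tab[(tab["fdr"] < fdr_thr) & (tab["log2fc"] > 0)].index
        sig_down = tab[(tab["fdr"] < fdr_thr) & (tab["log2fc"] < 0)].index
        for direction, sig in (("up", sig_up), ("down", sig_down)):
            calls = set()
            for feat in sig:
                ok = True
                for o in others:
                    otab = de_by_cell_type[o].table
                    if feat not in otab.index:
                        continue
                    row = otab.loc[feat]
                    if not (row["p"] > p_thr):
                        ok = False
                        break
                    if direction == "up" and not (row["log2fc"] < fc_band):
                        ok = False
                        break
                    if direction == "down" and not (row["log2fc"] > -fc_band):
                        ok = False
                        break
                if ok:
                    calls.add(feat)
            if direction == "up":
                up = calls
            else:
                down = calls
        out[ct] = {"up": up, "down": down}
    return out
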