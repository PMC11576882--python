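"""Biopsy-cohort validation: average-Z pathway scoring with one-way ANOVA
across disease stages, SAM (significance analysis of microarrays)
differential expression with permutation FDR, and Spearman phenotype
correlation.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BiopsyCohort

logger = logging.getLogger("iromics.biopsy")


@dataclass
class PathwayScoreTable:
    scores: pd.Series  # per sample average Z
    groups: pd.Series
    genes_used: list[str]


@dataclass
class GroupComparison:
    f_stat: float
    p: float
    group_means: dict[str, float]


@dataclass
class SamResult:
    table: pd.DataFrame  # d, s, q per gene
    s0: float
    n_perm: int
    delta: float | None = None

    def significant(self, q_thr: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q"] < q_thr])


def pathway_zscore(cohort: BiopsyCohort, genes: set[str]) -> PathwayScoreTable:
    """Average per-gene Z-score over a gene set, per sample.

    Z-scores are computed across the pooled cohort (all groups including
    donors); genes absent from the cohort or with zero variance are logged
    and skipped.
    """
    present = [g for g in sorted(genes) if g in cohort.expression.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.info("pathway_zscore: %d genes absent from cohort", len(missing))
    arr = cohort.expression.loc[present].to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        drop = [present[i] for i in np.where(sd == 0)[0]]
        logger.info("pathway_zscore: dropping constant genes %s", drop)
        present = [g for g in present if g not in drop]
        arr = cohort.expression.loc[present].to_numpy(dtype=float)
        sd = arr.std(axis=1)
    if not present:
        raise ValueError("no usable genes overlap the cohort")
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    scores = pd.Series(z.mean(axis=0), index=cohort.expression.columns, name="z_avg")
    return PathwayScoreTable(scores=scores, groups=cohort.groups, genes_used=present)


def anova_groups(scores: PathwayScoreTable) -> GroupComparison:
    """One-way ANOVA of the pathway scores across groups."""
    by_group = {
        g: scores.scores[scores.groups == g].to_numpy()
        for g in scores.groups.unique()
    }
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    f, p = stats.f_oneway(*by_group.values())
    return GroupComparison(
        f_stat=float(f),
        p=float(p),
        group_means={g: float(v.mean()) for g, v in by_group.items()},
    )


def _sam_stats(
    arr: np.ndarray, g1: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """SAM d = (mean1 - mean2)/(s + s0) with the pooled gene-wise scatter s."""
    n1, n2 = int(g1.sum()), int((~g1).sum())
    m1 = arr[:, g1].mean(axis=1)
    m2 = arr[:, ~g1].mean(axis=1)
    ss1 = ((arr[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((arr[:, ~g1] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return (m1 - m2) / (s + s0), s


def choose_s0(r: np.ndarray, s: np.ndarray, n_windows: int | None = None) -> float:
    """Fudge factor from the percentile grid of s minimising the coefficient
    of variation of the window-wise median absolute deviation of d.

    Grid: percentiles 0, 5, ..., 100 of s; windows are s-quantile bins.
    """
    n = len(s)
    if n_windows is None:
        n_windows = min(100, max(3, n // 10))
    order = np.argsort(s, kind="mergesort")
    bins = np.array_split(order, n_windows)
    alphas = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = 0.0, np.inf
    for s0 in alphas:
        d = r / (s + s0)
        vs = np.array(
            [stats.median_abs_deviation(d[b], scale="normal") for b in bins if len(b) > 1]
        )
        mu = vs.mean()
        if mu == 0:
            continue
        cv = vs.std(ddof=1) / mu
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_two_class(
    expression: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 200,
    seed: int = 0,
    s0: float | None = None,
    exhaustive: bool = False,
) -> SamResult:
    """Two-class unpaired SAM with permutation-based per-gene FDR.

    q_i = median over permutations of #{null |d*| >= |d_i|} divided by the
    observed count #{|d| >= |d_i|}, made monotone non-decreasing in rank of
    |d| and clipped to [0, 1].  With ``exhaustive=True`` every group
    relabelling is enumerated (feasible at small n).  ``s0=0`` reduces |d| to
    the ordinary unpaired t ordering.
    """
    labels = groups.reindex(expression.columns)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("SAM two-class needs exactly two groups")
    g1 = (labels == classes[0]).to_numpy()
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    arr = expression.to_numpy(dtype=float)
    n = arr.shape[1]
    n1 = int(g1.sum())

    m1 = arr[:, g1].mean(axis=1)
    m2 = arr[:, ~g1].mean(axis=1)
    r = m1 - m2
    _, s = _sam_stats(arr, g1, 0.0)
    if (s == 0).any():
        logger.info("sam: %d zero-scatter genes floored by s0", int((s == 0).sum()))
    if s0 is None:
        s0 = choose_s0(r, s)
    d_obs = r / (s + s0)

    if exhaustive:
        combos = list(itertools.combinations(range(n), n1))
        perms = []
        for c in combos:
            mask = np.zeros(n, dtype=bool)
            mask[list(c)] = True
            perms.append(mask)
    else:
        rng = np.random.default_rng(seed)
        perms = []
        for _ in range(n_perm):
            idx = rng.choice(n, size=n1, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            perms.append(mask)

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="mergesort")
    thresholds = abs_obs[order]
    obs_counts = np.arange(1, len(thresholds) + 1)  # #{|d| >= threshold_k}

    null_counts = np.empty((len(perms), len(thresholds)))
    for b, mask in enumerate(perms):
        d_null, _ = _sam_stats(arr, mask, s0)
        a = np.sort(np.abs(d_null))
        # count of null |d*| >= t for each threshold t (descending t)
        null_counts[b] = len(a) - np.searchsorted(a, thresholds, side="left")
    med_false = np.median(null_counts, axis=0)
    q_sorted = np.clip(med_false / obs_counts, 0.0, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone in rank of |d|
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    table = pd.DataFrame({"d": d_obs, "s": s, "q": q}, index=expression.index)
    return SamResult(table=table, s0=float(s0), n_perm=len(perms))


def spearman_phenotypes(
    cohort: BiopsyCohort,
    genes: list[str],
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman rank correlation (midrank ties) between gene expression and
    per-sample phenotypes, with two-sided p-values."""
    phenos = phenotypes or list(cohort.phenotypes.columns)
    rows = []
    for g in genes:
        if g not in cohort.expression.index:
            logger.info("spearman: gene %s absent from cohort", g)
            continue
        x = cohort.expression.loc[g].to_numpy(dtype=float)
        for ph in phenos:
            y = cohort.phenotypes[ph].to_numpy(dtype=float)
            if len(x) < 3:
                raise ValueError("need at least 3 paired observations")
            if np.all(y == y[0]) or np.all(x == x[0]):
                logger.info("spearman: constant input for (%s, %s)", g, ph)
                rows.append({"gene": g, "phenotype": ph, "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"gene": g, "phenotype": ph, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)
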