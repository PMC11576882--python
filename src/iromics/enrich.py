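"""Ranking construction, preranked gene-set enrichment (weighted
Kolmogorov-Smirnov running sum with gene-label permutation), hypergeometric
over-representation, and semantic-similarity clustering of enriched terms.

Two ranking kinds feed the same enrichment engine: the signal2noise ratio
(mu1 - mu2)/(sigma1 + sigma2) from each cell type's differential analysis,
and the per-feature loadings of the consensus OPLS model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .datatypes import NormalizedMatrix
from .diffexpr import bh_adjust
from .ontology import Ontology, wang_similarity  # re-exported

__all__ = [
    "RankedList",
    "signal2noise_ranking",
    "loading_ranking",
    "gsea_preranked",
    "ora_hypergeometric",
    "wang_similarity",
    "cluster_and_filter_terms",
]

logger = logging.getLogger("iromics.enrich")


@dataclass
class RankedList:
    """Feature scores sorted descending (ties broken by feature id)."""

    scores: pd.Series
    score_kind: str  # signal2noise | opls_loading

    def __post_init__(self) -> None:
        s = self.scores
        if s.index.has_duplicates:
            raise ValueError("duplicate feature ids in ranking")
        order = sorted(s.index, key=lambda f: (-s[f], f))
        self.scores = s.loc[order]


def signal2noise_ranking(
    matrix: NormalizedMatrix, groups: np.ndarray | None = None
) -> RankedList:
    """Signal2noise ratio (insulin_resistant vs basal) per feature.

    Each group standard deviation is floored at max(0.2*|mean|, 0.2) so
    near-constant features cannot dominate the ranking.
    """
    labels = groups if groups is not None else matrix.condition_labels()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("signal2noise needs exactly two groups")
    arr = matrix.values.to_numpy(dtype=float)
    g1 = labels == "insulin_resistant" if "insulin_resistant" in classes else labels == classes[1]
    g2 = ~g1
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = arr[:, g1].mean(axis=1), arr[:, g2].mean(axis=1)
    s1, s2 = arr[:, g1].std(axis=1, ddof=1), arr[:, g2].std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 0.2))
    s2 = np.maximum(s2, np.maximum(0.2 * np.abs(m2), 0.2))
    score = (m1 - m2) / (s1 + s2)
    return RankedList(pd.Series(score, index=matrix.feature_ids), "signal2noise")


def loading_ranking(loadings: pd.Series, layer: str) -> RankedList:
    """Ranking from the consensus-model loadings of one block."""
    prefix = f"{layer}:"
    sub = loadings[[i for i in loadings.index if i.startswith(prefix)]]
    sub.index = [i[len(prefix):] for i in sub.index]
    return RankedList(sub, "opls_loading")


def _es_batch(pos2d: np.ndarray, absw: np.ndarray, n: int) -> np.ndarray:
    """Signed running-sum extreme for many hit-position rows at once.

    Each row of ``pos2d`` holds the sorted 0-based ranks of one gene set's
    members; increments are proportional to |score|^weight at hits, decrements
    uniform across misses.
    """
    b, m = pos2d.shape
    w = absw[pos2d]
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] <= 0
    if zero.any():
        w[zero] = 1.0
        total = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) / total
    k = np.arange(m)
    miss = (pos2d - k) / (n - m)
    post = cw - miss                      # running sum right after each hit
    pre = (cw - w / total) - miss         # right before each hit
    hi = post.max(axis=1)
    lo = pre.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def _es_from_positions(
    pos: np.ndarray, absw: np.ndarray, n: int
) -> tuple[float, int]:
    """Signed extreme of the weighted running sum given sorted hit positions.

    Returns (ES, index of the extremum in the hit list; negative index
    convention not needed because the position array is returned sorted).
    """
    m = pos.size
    w = absw[pos]
    total = w.sum()
    if total <= 0:
        w = np.ones(m)
        total = float(m)
    cw = np.cumsum(w) / total
    k = np.arange(m)
    miss_before = (pos - k) / (n - m)
    post = cw - (pos + 1 - (k + 1)) / (n - m)  # running sum right after each hit
    pre = np.concatenate(([0.0], cw[:-1])) - miss_before  # right before each hit
    i_max = int(np.argmax(post))
    i_min = int(np.argmin(pre))
    if post[i_max] >= -pre[i_min]:
        return float(post[i_max]), i_max
    return float(pre[i_min]), i_min


def gsea_preranked(
    ranking: RankedList,
    gene_sets: dict[str, set[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutation.

    ES is the extreme deviation of the running sum whose hit increments are
    proportional to |score|^weight and miss decrements uniform.  The nominal
    p-value and NES come from random same-size gene sets: NES = ES divided by
    the mean |null ES| of matching sign, p is the same-sign exceedance
    fraction (add-one smoothed).  q is Benjamini-Hochberg within this call.
    Returns one row per retained set with the leading-edge members.
    """
    rng = np.random.default_rng(seed)
    ids = list(ranking.scores.index)
    scores = ranking.scores.to_numpy(dtype=float)
    n = len(ids)
    absw = np.abs(scores) ** weight
    index_of = {g: i for i, g in enumerate(ids)}

    # one shared label permutation per draw; a size-m null set is the sorted
    # prefix of each permuted row (sampling without replacement)
    perm_matrix = np.argsort(rng.random((n_perm, n)), axis=1)
    null_cache: dict[int, np.ndarray] = {}

    def null_es(m: int) -> np.ndarray:
        if m not in null_cache:
            pos2d = np.sort(perm_matrix[:, :m], axis=1)
            null_cache[m] = _es_batch(pos2d, absw, n)
        return null_cache[m]

    rows = []
    for sid in sorted(gene_sets):
        members = sorted(set(gene_sets[sid]) & set(ids))
        if len(members) < min_size or len(members) > max_size or len(members) >= n:
            if not members:
                logger.info("gsea: set %s has no overlap with the ranking", sid)
            continue
        pos = np.sort(np.array([index_of[g] for g in members]))
        es, i_ext = _es_from_positions(pos, absw, n)
        null = null_es(len(members))
        if es >= 0:
            same = null[null >= 0]
            p = (1.0 + float(np.sum(same >= es))) / (1.0 + len(same))
            denom = same.mean() if len(same) else np.nan
        else:
            same = null[null < 0]
            p = (1.0 + float(np.sum(same <= es))) / (1.0 + len(same))
            denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        if es >= 0:
            lead = [ids[j] for j in pos[: i_ext + 1]]
        else:
            lead = [ids[j] for j in pos[i_ext:]]
        rows.append(
            {
                "set_id": sid,
                "size": len(members),
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(lead),
            }
        )
    out = pd.DataFrame(rows).set_index("set_id") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "leading_edge"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def ora_hypergeometric(
    selected: set[str], target_set: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """One-sided hypergeometric over-representation test.

    Returns (upper-tail p, fold enrichment, overlap size).
    """
    if not universe:
        raise ValueError("empty universe")
    sel = set(selected) & set(universe)
    tgt = set(target_set) & set(universe)
    overlap = len(sel & tgt)
    m_u, n_sel, n_tgt = len(universe), len(sel), len(tgt)
    p = float(hypergeom.sf(overlap - 1, m_u, n_tgt, n_sel))
    expected = n_tgt / m_u * n_sel
    fold = overlap / expected if expected > 0 else np.nan
    return p, fold, overlap


def cluster_and_filter_terms(
    results: dict[tuple[str, str, str], pd.DataFrame],
    ontology: Ontology,
    p_thr: float = 0.05,
    q_thr: float = 0.1,
    cut_distance: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray | None]:
    """Filter enriched terms and cluster them by Wang similarity.

    ``results`` maps (cell_type, layer, ranking_kind) -> per-set enrichment
    table.  A term is retained when, in at least one cell type, BOTH omics
    layers reach p < p_thr and q < q_thr under either ranking kind.  Retained
    terms are clustered with average linkage on 1 - Wang similarity.
    Returns (NES matrix terms x conditions, cluster labels, linkage matrix).
    """
    if not results:
        raise ValueError("no enrichment results supplied")
    cell_types = sorted({ct for ct, _, _ in results})
    layers = sorted({ly for _, ly, _ in results})
    all_terms = sorted(set().union(*(set(df.index) for df in results.values())))

    def passes(term: str, ct: str, layer: str) -> bool:
        for (c, l, kind), df in results.items():
            if c == ct and l == layer and term in df.index:
                row = df.loc[term]
                if row["p"] < p_thr and row["q"] < q_thr:
                    return True
        return False

    retained = [
        t
        for t in all_terms
        if any(all(passes(t, ct, ly) for ly in layers) for ct in cell_types)
    ]
    if not retained:
        logger.warning("no term passed the significance filter")
        return pd.DataFrame(), pd.Series(dtype=int), None

    cols = sorted(results)
    nes = pd.DataFrame(
        {
            "|".join(c): [
                results[c].loc[t, "nes"] if t in results[c].index else np.nan
                for t in retained
            ]
            for c in cols
        },
        index=retained,
    )
    if len(retained) == 1:
        return nes, pd.Series([1], index=retained), None
    k = len(retained)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = 1.0 - wang_similarity(retained[i], retained[j], ontology)
            dist[i, j] = dist[j, i] = d
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=cut_distance, criterion="distance")
    return nes, pd.Series(labels, index=retained), z
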