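"""Consensus feature selection across cell types (the "Top 40"-style rule)
and hierarchical clustering for the combined fold-change heatmap.

A feature passes in one cell type when it is both important to the multiblock
discrimination (VIP > 1) and significantly regulated (FDR < 0.1) in at least
one omics layer; features passing in enough cell types with a consistent
direction of regulation are selected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import DEResult


@dataclass
class FeatureSelection:
    table: pd.DataFrame  # pass_count, mean_vip, direction_consistent, selected, rank
    vip_thr: float
    fdr_thr: float
    min_comparisons: int

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def consensus_top_features(
    vip_by_cell_type: dict[str, pd.Series],
    de_results: dict[tuple[str, str], DEResult],
    vip_thr: float = 1.0,
    fdr_thr: float = 0.1,
    min_comparisons: int = 3,
    comparisons: str = "cell_type",
) -> FeatureSelection:
    """Select features consistently regulated across cell types.

    ``vip_by_cell_type`` maps cell type -> VIP series indexed by
    ``layer:feature`` (concatenated-block scale); ``de_results`` maps
    (cell_type, layer) -> DEResult.  A feature passes a comparison when
    VIP > vip_thr (strict) and FDR < fdr_thr in the same layer.  With
    ``comparisons="cell_type"`` (default) a cell type counts once if any
    layer passes; ``"cell_type_layer"`` counts each layer separately.
    Selection additionally requires one sign of log2fc across every passing
    comparison.
    """
    if comparisons not in ("cell_type", "cell_type_layer"):
        raise ValueError("comparisons must be 'cell_type' or 'cell_type_layer'")
    cell_types = sorted(vip_by_cell_type)
    layers = sorted({layer for (_, layer) in de_results})
    for ct in cell_types:
        for layer in layers:
            if (ct, layer) not in de_results:
                raise ValueError(f"missing DE result for ({ct}, {layer})")

    features = sorted(
        set().union(*(set(de_results[(ct, layer)].table.index) for ct in cell_types for layer in layers))
    )
    rows = []
    for feat in features:
        pass_count = 0
        vips: list[float] = []
        signs: set[int] = set()
        for ct in cell_types:
            layer_passes = []
            for layer in layers:
                tab = de_results[(ct, layer)].table
                key = f"{layer}:{feat}"
                vip = vip_by_cell_type[ct].get(key, np.nan)
                if feat not in tab.index or not np.isfinite(vip):
                    continue
                fdr = tab.loc[feat, "fdr"]
                if vip > vip_thr and fdr < fdr_thr:
                    layer_passes.append(layer)
                    vips.append(float(vip))
                    lfc = tab.loc[feat, "log2fc"]
                    if lfc != 0:
                        signs.add(1 if lfc > 0 else -1)
            if comparisons == "cell_type":
                pass_count += 1 if layer_passes else 0
            else:
                pass_count += len(layer_passes)
        consistent = len(signs) <= 1
        selected = pass_count >= min_comparisons and consistent
        rows.append(
            {
                "feature": feat,
                "pass_count": pass_count,
                "mean_vip": float(np.mean(vips)) if vips else 0.0,
                "direction_consistent": consistent,
                "selected": selected,
            }
        )
    table = pd.DataFrame(rows).set_index("feature")
    order = table.sort_values(
        ["pass_count", "mean_vip"], ascending=[False, False], kind="mergesort"
    ).index
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    return FeatureSelection(
        table=table, vip_thr=vip_thr, fdr_thr=fdr_thr, min_comparisons=min_comparisons
    )


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.left, labels)
    right = _newick(node.right, labels)
    dl = node.dist - node.left.dist
    dr = node.dist - node.right.dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_feature_heatmap(
    log2fc: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
) -> tuple[list[str], np.ndarray, str]:
    """Agglomerative clustering of the selected-feature fold-change matrix.

    Rows are pre-sorted by feature id so ties break deterministically.
    Returns (dendrogram leaf order, linkage matrix, newick string).
    """
    if log2fc.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    mat = log2fc.sort_index()
    dist = pdist(mat.to_numpy(dtype=float), metric=metric)
    z = hierarchy.linkage(dist, method=linkage)
    leaves = hierarchy.leaves_list(z)
    order = [mat.index[i] for i in leaves]
    tree = hierarchy.to_tree(z)
    newick = _newick(tree, list(mat.index)) + ";"
    return order, z, newick


def score_selection(
    selection: FeatureSelection, shared_genes: set[str]
) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of the selected set against
    the planted consistently-regulated genes."""
    selected = set(selection.selected)
    tp = len(selected & shared_genes)
    sens = tp / len(shared_genes) if shared_genes else np.nan
    fdp = (len(selected) - tp) / len(selected) if selected else 0.0
    return sens, fdp
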