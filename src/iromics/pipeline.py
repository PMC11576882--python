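"""Full-pipeline orchestration: simulate (optional) -> preprocess -> DE ->
consensus OPLS -> consensus feature selection -> enrichment -> biopsy
validation, with every intermediate written as a plain-text table and a JSON
manifest tying the run together.

All randomness derives from the single configured seed; rerunning with the
same config yields byte-identical result tables (timings excluded).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biopsy as biopsy_mod
from . import io as iio
from .copls import consensus_opls_da
from .datatypes import DEResult
from .diffexpr import cell_specific_features, fc_correlation, fit_moderated_de, global_bh_adjust
from .enrich import (
    cluster_and_filter_terms,
    gsea_preranked,
    loading_ranking,
    ora_hypergeometric,
    signal2noise_ranking,
)
from .ontology import read_gmt, read_obo, write_gmt, write_obo
from .preprocess import normalize_protein, normalize_rna, pca_overview
from .select import cluster_feature_heatmap, consensus_top_features, score_selection
from .sim import BiopsyConfig, SimConfig, simulate_biopsy_cohort, simulate_ontology_and_sets, simulate_paired_omics

logger = logging.getLogger("iromics.pipeline")

STAGES = ("simulate", "preprocess", "de", "copls", "select", "enrich", "validate")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    n_terms: int = 30
    fdr_thr: float = 0.05
    select_fdr_thr: float = 0.1
    vip_thr: float = 1.0
    p_thr: float = 0.05
    q_thr: float = 0.1
    fc_band: float = 0.1
    min_comparisons: int = 3
    n_pred: int = 1
    n_orth: int = 1
    k_folds: int = 7
    n_perm: int = 1000          # consensus-model permutations
    gsea_n_perm: int = 1000
    sam_n_perm: int = 200
    biopsy_n_per_group: int = 20

    def validate(self) -> None:
        for name in ("fdr_thr", "select_fdr_thr", "p_thr", "q_thr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.vip_thr < 0 or self.fc_band < 0:
            raise ValueError("vip_thr and fc_band must be non-negative")
        if self.min_comparisons < 1:
            raise ValueError("min_comparisons must be >= 1")
        for name in ("k_folds", "n_perm", "gsea_n_perm", "sam_n_perm", "n_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_pred != 1:
            raise ValueError("only 1 predictive component is supported for a two-class response")
        SimConfig(**self.sim, seed=self.seed).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(**self.sim, seed=self.seed)


class Pipeline:
    """Stage-wise pipeline over a single output directory.

    Each stage reads its inputs from memory when the previous stage ran in
    this process, otherwise from the files the previous stage wrote, so runs
    can resume stage by stage.
    """

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: list[str] = []
        self.timings: dict[str, float] = {}
        self._mem: dict[str, object] = {}

    # ---- helpers -------------------------------------------------------
    def _record(self, *paths: Path) -> None:
        for p in paths:
            rel = str(Path(p).relative_to(self.out))
            if rel not in self.files:
                self.files.append(rel)

    def _cell_types(self) -> list[str]:
        return self.cfg.sim_config().cell_types()

    def _load_omics(self, layer: str) -> dict[str, object]:
        key = f"omics_{layer}"
        if key not in self._mem:
            data = {}
            for ct in self._cell_types():
                prefix = self.out / f"{layer}_{ct}"
                if not prefix.with_suffix(".tsv").exists():
                    raise FileNotFoundError(f"stage 'simulate' output missing: {prefix}.tsv")
                data[ct] = iio.read_omics(prefix, layer)
            self._mem[key] = data
        return self._mem[key]  # type: ignore[return-value]

    def _load_normalized(self) -> dict[tuple[str, str], object]:
        if "normalized" not in self._mem:
            from .datatypes import NormalizedMatrix

            normalized = {}
            for ct in self._cell_types():
                for layer in ("rna", "protein"):
                    path = self.out / f"normalized_{layer}_{ct}.tsv"
                    if not path.exists():
                        raise FileNotFoundError(f"stage 'preprocess' output missing: {path}")
                    values = iio.read_matrix_tsv(path)
                    samples = iio.read_samples_tsv(
                        self.out / (f"{layer}_{ct}" + ".samples.tsv")
                    )
                    normalized[(ct, layer)] = NormalizedMatrix(
                        values=values,
                        norm_factors=pd.Series(1.0, index=list(values.columns)),
                        samples=samples,
                        layer=layer,
                    )
            self._mem["normalized"] = normalized
        return self._mem["normalized"]  # type: ignore[return-value]

    def _load_de(self) -> dict[tuple[str, str], DEResult]:
        if "de" not in self._mem:
            de: dict[tuple[str, str], DEResult] = {}
            for layer in ("rna", "protein"):
                path = self.out / f"de_{layer}.tsv"
                if not path.exists():
                    raise FileNotFoundError(f"stage 'de' output missing: {path}")
                combined = pd.read_csv(path, sep="\t", index_col="feature")
                for ct, sub in combined.groupby("cell_type"):
                    de[(str(ct), layer)] = DEResult(
                        table=sub[["log2fc", "t", "p", "fdr"]],
                        cell_type=str(ct),
                        layer=layer,
                        residual_df=np.nan,
                        prior_df=np.nan,
                        prior_var=np.nan,
                    )
            self._mem["de"] = de
        return self._mem["de"]  # type: ignore[return-value]

    def _load_vip(self) -> dict[str, pd.Series]:
        if "vip_tables" not in self._mem:
            models = self._mem.get("models")
            if models is not None:
                self._mem["vip_tables"] = {ct: m.vip for ct, m in models.items()}
            else:
                vip = {}
                for ct in self._cell_types():
                    path = self.out / f"vip_{ct}.tsv"
                    if not path.exists():
                        raise FileNotFoundError(f"stage 'copls' output missing: {path}")
                    vip[ct] = pd.read_csv(path, sep="\t", index_col="feature")["vip"]
                self._mem["vip_tables"] = vip
        return self._mem["vip_tables"]  # type: ignore[return-value]

    def _load_loadings(self) -> dict[str, pd.Series]:
        models = self._mem.get("models")
        if models is not None:
            return {ct: m.loadings for ct, m in models.items()}
        out = {}
        for ct in self._cell_types():
            path = self.out / f"vip_{ct}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"stage 'copls' output missing: {path}")
            out[ct] = pd.read_csv(path, sep="\t", index_col="feature")["loading"]
        return out

    def _load_selection(self):
        if "selection" not in self._mem:
            path = self.out / "selection.tsv"
            if not path.exists():
                return None
            from .select import FeatureSelection

            table = pd.read_csv(path, sep="\t", index_col="feature")
            self._mem["selection"] = FeatureSelection(
                table=table,
                vip_thr=self.cfg.vip_thr,
                fdr_thr=self.cfg.select_fdr_thr,
                min_comparisons=self.cfg.min_comparisons,
            )
        return self._mem.get("selection")

    def _load_enrichment(self) -> dict[tuple[str, str, str], pd.DataFrame]:
        if "enrichment" not in self._mem:
            path = self.out / "enrichment.tsv"
            if not path.exists():
                raise FileNotFoundError(f"stage 'enrich' output missing: {path}")
            combined = pd.read_csv(path, sep="\t", index_col="set_id")
            results = {
                (str(ct), str(layer), str(kind)): sub.drop(
                    columns=["cell_type", "layer", "ranking"]
                )
                for (ct, layer, kind), sub in combined.groupby(
                    ["cell_type", "layer", "ranking"]
                )
            }
            self._mem["enrichment"] = results
        return self._mem["enrichment"]  # type: ignore[return-value]

    def _load_truth(self):
        if "truth" not in self._mem:
            path = self.out / "truth.json"
            if path.exists():
                self._mem["truth"] = iio.read_truth_json(path)
        return self._mem.get("truth")

    # ---- stages --------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg.sim_config()
        paired = simulate_paired_omics(cfg)
        for ct in self._cell_types():
            self._record(*iio.write_omics(paired.rna[ct], self.out / f"rna_{ct}"))
            self._record(*iio.write_omics(paired.protein[ct], self.out / f"protein_{ct}"))
        onto, gene_sets, planted_terms = simulate_ontology_and_sets(
            self.cfg.n_terms,
            self.cfg.sim_config().n_genes,
            seed=self.cfg.seed + 1,
            planted_genes=paired.truth.biopsy_shifted_genes or None,
        )
        paired.truth.enriched_sets = set(planted_terms)
        write_gmt(gene_sets, self.out / "gene_sets.gmt")
        write_obo(onto, self.out / "ontology.obo")
        iio.write_truth_json(paired.truth, self.out / "truth.json")
        cohort = simulate_biopsy_cohort(
            [f"g{i:04d}" for i in range(cfg.n_genes)],
            paired.truth,
            BiopsyConfig(n_per_group=self.cfg.biopsy_n_per_group),
            seed=self.cfg.seed + 2,
        )
        self._record(*iio.write_biopsy(cohort, self.out))
        self._record(
            self.out / "gene_sets.gmt", self.out / "ontology.obo", self.out / "truth.json"
        )
        self._mem["omics_rna"] = paired.rna
        self._mem["omics_protein"] = paired.protein
        self._mem["truth"] = paired.truth
        self._mem["ontology"] = onto
        self._mem["gene_sets"] = gene_sets
        self._mem["cohort"] = cohort

    def stage_preprocess(self) -> None:
        rna = self._load_omics("rna")
        protein = self._load_omics("protein")
        normalized: dict[tuple[str, str], object] = {}
        pca_frames = {}
        for ct in self._cell_types():
            normalized[(ct, "rna")] = normalize_rna(rna[ct])
            normalized[(ct, "protein")] = normalize_protein(protein[ct])
        for (ct, layer), nm in normalized.items():
            path = self.out / f"normalized_{layer}_{ct}.tsv"
            iio.write_matrix_tsv(nm.values, path)
            self._record(path)
        for layer in ("rna", "protein"):
            joined = pd.concat(
                [normalized[(ct, layer)].values for ct in self._cell_types()],
                axis=1,
                join="inner",
            )
            summary = pca_overview(joined, n_components=2)
            tab = summary.scores.copy()
            tab["variance_explained_PC1"] = summary.variance_explained[0]
            tab["variance_explained_PC2"] = summary.variance_explained[1]
            pca_frames[layer] = tab
            path = self.out / f"pca_{layer}.tsv"
            tab.to_csv(path, sep="\t", index_label="sample_id")
            self._record(path)
        self._mem["normalized"] = normalized
        self._mem["pca"] = pca_frames

    def stage_de(self) -> None:
        normalized = self._load_normalized()
        de: dict[tuple[str, str], DEResult] = {}
        for layer in ("rna", "protein"):
            results = [
                fit_moderated_de(normalized[(ct, layer)], cell_type=ct)
                for ct in self._cell_types()
            ]
            global_bh_adjust(results)
            for r in results:
                de[(r.cell_type, layer)] = r
            combined = pd.concat(
                [r.table.assign(cell_type=r.cell_type, layer=layer) for r in results]
            )
            path = self.out / f"de_{layer}.tsv"
            combined.to_csv(path, sep="\t", index_label="feature")
            self._record(path)
        corr_rows = []
        for ct in self._cell_types():
            c = fc_correlation(de[(ct, "rna")], de[(ct, "protein")])
            corr_rows.append({"cell_type": ct, "r": c.r, "n_features": c.n_features})
        path = self.out / "fc_correlation.tsv"
        pd.DataFrame(corr_rows).to_csv(path, sep="\t", index=False)
        self._record(path)
        for layer in ("rna", "protein"):
            calls = cell_specific_features(
                {ct: de[(ct, layer)] for ct in self._cell_types()},
                p_thr=self.cfg.p_thr,
                fc_band=self.cfg.fc_band,
                fdr_thr=self.cfg.select_fdr_thr,
            )
            path = self.out / f"cell_specific_{layer}.json"
            with open(path, "w") as fh:
                json.dump(
                    {ct: {d: sorted(v) for d, v in dd.items()} for ct, dd in calls.items()},
                    fh,
                    indent=1,
                    sort_keys=True,
                )
            self._record(path)
        self._mem["de"] = de

    def stage_copls(self) -> None:
        normalized = self._load_normalized()
        models = {}
        summary = {}
        for i, ct in enumerate(self._cell_types()):
            model = consensus_opls_da(
                normalized[(ct, "rna")],
                normalized[(ct, "protein")],
                n_orth=self.cfg.n_orth,
                k_folds=self.cfg.k_folds,
                n_perm=self.cfg.n_perm,
                seed=self.cfg.seed + 10 + i,
            )
            models[ct] = model
            summary[ct] = {
                "r2y": model.r2y,
                "q2": model.q2,
                "perm_p": model.perm_p,
                "perm_t_p": model.perm_t_p,
                "block_contributions": model.block_contributions,
                "block_rv_pred": model.block_rv_pred,
            }
            tab = pd.DataFrame({"vip": model.vip, "loading": model.loadings})
            path = self.out / f"vip_{ct}.tsv"
            tab.to_csv(path, sep="\t", index_label="feature")
            self._record(path)
        path = self.out / "copls_summary.json"
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        self._record(path)
        self._mem["models"] = models

    def stage_select(self) -> None:
        de = self._load_de()
        vip_by_ct = self._load_vip()
        selection = consensus_top_features(
            vip_by_ct,
            de,
            vip_thr=self.cfg.vip_thr,
            fdr_thr=self.cfg.select_fdr_thr,
            min_comparisons=self.cfg.min_comparisons,
        )
        path = self.out / "selection.tsv"
        selection.table.to_csv(path, sep="\t", index_label="feature")
        self._record(path)
        selected = selection.selected
        if len(selected) >= 2:
            cols = {}
            for (ct, layer), res in sorted(de.items()):
                cols[f"{ct}|{layer}"] = res.table["log2fc"].reindex(selected)
            lfc = pd.DataFrame(cols).fillna(0.0)
            order, _, newick = cluster_feature_heatmap(lfc)
            with open(self.out / "selection_dendrogram.newick", "w") as fh:
                fh.write(newick + "\n")
            path2 = self.out / "selection_log2fc.tsv"
            lfc.loc[order].to_csv(path2, sep="\t", index_label="feature")
            self._record(self.out / "selection_dendrogram.newick", path2)
        truth = self._load_truth()
        if truth is not None:
            sens, fdp = score_selection(selection, truth.shared_genes)
            with open(self.out / "selection_recovery.json", "w") as fh:
                json.dump({"sensitivity": sens, "fdp": fdp}, fh, indent=1, sort_keys=True)
            self._record(self.out / "selection_recovery.json")
        self._mem["selection"] = selection

    def stage_enrich(self) -> None:
        normalized = self._load_normalized()
        de = self._load_de()
        loadings = self._load_loadings()
        gene_sets = self._mem.get("gene_sets") or read_gmt(self.out / "gene_sets.gmt")
        onto = self._mem.get("ontology") or read_obo(self.out / "ontology.obo")
        results = {}
        rows = []
        for i, ct in enumerate(self._cell_types()):
            for layer in ("rna", "protein"):
                rankings = {
                    "signal2noise": signal2noise_ranking(normalized[(ct, layer)]),
                    "opls_loading": loading_ranking(loadings[ct], layer),
                }
                for kind, ranking in rankings.items():
                    df = gsea_preranked(
                        ranking,
                        gene_sets,
                        n_perm=self.cfg.gsea_n_perm,
                        seed=self.cfg.seed + 100 + i,
                        min_size=5,
                        max_size=max(50, self.cfg.sim_config().n_genes // 4),
                    )
                    results[(ct, layer, kind)] = df
                    rows.append(df.assign(cell_type=ct, layer=layer, ranking=kind))
        combined = pd.concat(rows)
        path = self.out / "enrichment.tsv"
        combined.to_csv(path, sep="\t", index_label="set_id")
        self._record(path)

        nes, clusters, _ = cluster_and_filter_terms(
            results, onto, p_thr=self.cfg.p_thr, q_thr=self.cfg.q_thr
        )
        tab = nes.copy()
        tab["cluster"] = clusters
        path = self.out / "terms_retained.tsv"
        tab.to_csv(path, sep="\t", index_label="set_id")
        self._record(path)

        # over-representation of the selected features in each planted set
        selection = self._load_selection()
        if selection is not None and selection.selected:
            universe = set().union(
                *(set(de[(ct, "rna")].table.index) for ct in self._cell_types())
            )
            ora_rows = []
            for sid in sorted(gene_sets):
                p, fold, overlap = ora_hypergeometric(
                    set(selection.selected), gene_sets[sid], universe
                )
                ora_rows.append({"set_id": sid, "p": p, "fold": fold, "overlap": overlap})
            path = self.out / "ora_selected.tsv"
            pd.DataFrame(ora_rows).to_csv(path, sep="\t", index=False)
            self._record(path)
        self._mem["enrichment"] = results
        self._mem["retained_terms"] = (nes, clusters)

    def stage_validate(self) -> None:
        cohort = self._mem.get("cohort")
        if cohort is None:
            cohort = iio.read_biopsy(self.out)
        results = self._load_enrichment()
        # core-enrichment genes of retained terms, falling back to selection
        core: set[str] = set()
        retained_path = self.out / "terms_retained.tsv"
        if "retained_terms" in self._mem:
            retained_ids = list(self._mem["retained_terms"][0].index)
        elif retained_path.exists():
            retained_ids = list(
                pd.read_csv(retained_path, sep="\t", index_col="set_id").index
            )
        else:
            retained_ids = []
        for (ct, layer, kind), df in results.items():
            for term in retained_ids:
                if term in df.index and df.loc[term, "nes"] > 0:
                    core |= set(str(df.loc[term, "leading_edge"]).split(","))
        selection = self._load_selection()
        if not core and selection is not None:
            core = set(selection.selected)
        if not core:
            truth = self._load_truth()
            core = set(truth.biopsy_shifted_genes) if truth else set()
        if not core:
            raise ValueError("no core-enrichment genes available for validation")

        score = biopsy_mod.pathway_zscore(cohort, core)
        path = self.out / "pathway_scores.tsv"
        tab = pd.DataFrame({"z_avg": score.scores, "group": score.groups})
        tab.to_csv(path, sep="\t", index_label="sample_id")
        self._record(path)
        comp = biopsy_mod.anova_groups(score)
        with open(self.out / "pathway_anova.json", "w") as fh:
            json.dump(
                {"F": comp.f_stat, "p": comp.p, "group_means": comp.group_means},
                fh,
                indent=1,
                sort_keys=True,
            )
        self._record(self.out / "pathway_anova.json")

        sub = cohort.groups.isin(["LD", "advanced_DKD"])
        expr = cohort.expression.loc[:, sub.to_numpy()]
        sam = biopsy_mod.sam_two_class(
            expr,
            cohort.groups[sub],
            n_perm=self.cfg.sam_n_perm,
            seed=self.cfg.seed + 200,
        )
        path = self.out / "sam_advanced_vs_ld.tsv"
        sam.table.to_csv(path, sep="\t", index_label="gene")
        self._record(path)

        top = sorted(core)[:10]
        spear = biopsy_mod.spearman_phenotypes(cohort, top)
        path = self.out / "spearman_phenotypes.tsv"
        spear.to_csv(path, sep="\t", index=False)
        self._record(path)

    # ---- driver --------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.perf_counter()
            logger.info("stage %s: start (seed=%d)", stage, self.cfg.seed)
            getattr(self, f"stage_{stage}")()
            self.timings[stage] = time.perf_counter() - t0
            logger.info("stage %s: done in %.2fs", stage, self.timings[stage])
        manifest = {
            "config": asdict(self.cfg),
            "seed": self.cfg.seed,
            "stages": stages,
            "files": sorted(self.files),
            "timings": self.timings,
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the configured stages and return the output manifest."""
    return Pipeline(config).run(stages)
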