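"""Seeded generators for paired RNA/protein datasets, toy ontologies with
gene-set annotations, and a biopsy-style validation cohort.

The paired generator emulates the study design the pipeline assumes: several
kidney cell types measured under basal and insulin-resistant conditions with
a handful of biological replicates each, a block of genes regulated in every
cell type plus cell-type-specific blocks, and planted transcript/protein
effects that are correlated across layers. RNA counts are negative-binomial
around library-size-scaled gene baselines; protein intensities are log-normal.
Every planted effect is recorded in a :class:`~iromics.datatypes.SimTruth`
so recovery can be scored exactly.

Planted effects for a gene are drawn once per layer pair from a two-sided
bivariate normal: a random sign (shared by both layers when the target
cross-layer correlation is non-negative, opposed otherwise) times a
bivariate normal centred at ``effect_log2fc`` with spread
``effect_log2fc_sd``.  The jitter correlation is solved so that the overall
Pearson correlation of (RNA, protein) planted effects equals
``rna_protein_effect_corr`` exactly in expectation:

    rho_jitter = (|rho_target|*(mu^2 + sd^2) - mu^2) / sd^2,

clipped to [-1, 1] (an out-of-range solution, e.g. a near-zero target with a
tight spread, is clipped and logged as unattainable).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BiopsyCohort, OmicsMatrix, SampleMeta, SimTruth
from .ontology import Ontology, annotations_with_ancestors

DEFAULT_CELL_TYPES = ("Pod", "GEC", "MC", "PTC")
BIOPSY_GROUPS = ("LD", "early_DKD", "advanced_DKD")


@dataclass
class SimConfig:
    """Study-design and noise parameters of the paired-omics generator."""

    n_cell_types: int = 4
    n_replicates: int = 5
    n_genes: int = 2000
    n_shared_signal: int = 40
    n_specific_signal: int = 30
    effect_log2fc: float = 1.0       # mean planted effect magnitude, log2 units
    effect_log2fc_sd: float = 0.75   # spread of effect magnitudes around the mean
    rna_protein_effect_corr: float = 0.5
    rna_dispersion: float = 0.05     # NB dispersion (BCV^2) for cell-line replicates
    protein_cv: float = 0.2          # log2-scale sd of protein noise
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    batch_shift: float = 0.0         # additive log2 offset for the second batch
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cell_types", "n_replicates", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_shared_signal < 0 or self.n_specific_signal < 0:
            raise ValueError("signal counts must be non-negative")
        n_signal = self.n_shared_signal + self.n_cell_types * self.n_specific_signal
        if n_signal >= self.n_genes:
            raise ValueError(
                f"{n_signal} signal genes do not fit into {self.n_genes} genes"
            )
        if not -1.0 <= self.rna_protein_effect_corr <= 1.0:
            raise ValueError("rna_protein_effect_corr must lie in [-1, 1]")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("lib_size_range must be positive and ordered")

    def cell_types(self) -> list[str]:
        names = list(DEFAULT_CELL_TYPES[: self.n_cell_types])
        names += [f"CT{i + 1}" for i in range(len(names), self.n_cell_types)]
        return names


@dataclass
class PairedOmics:
    """Per-cell-type paired RNA/protein matrices plus ground truth."""

    rna: dict[str, OmicsMatrix]
    protein: dict[str, OmicsMatrix]
    truth: SimTruth


def _draw_effect_pair(rng: np.random.Generator, cfg: SimConfig) -> tuple[float, float]:
    mu, sd = cfg.effect_log2fc, cfg.effect_log2fc_sd
    rho_t = cfg.rna_protein_effect_corr
    if sd <= 0:
        sign = -1.0 if rng.random() < 0.5 else 1.0
        return sign * mu, sign * mu * (1.0 if rho_t >= 0 else -1.0)
    rho_j = (abs(rho_t) * (mu * mu + sd * sd) - mu * mu) / (sd * sd)
    rho_j = float(np.clip(rho_j, -1.0, 1.0))
    cov = sd * sd * np.array([[1.0, rho_j], [rho_j, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, method="cholesky")
    sign = -1.0 if rng.random() < 0.5 else 1.0
    e_rna = sign * (mu + z[0])
    e_prot = sign * (1.0 if rho_t >= 0 else -1.0) * (mu + z[1])
    return float(e_rna), float(e_prot)


def simulate_paired_omics(config: SimConfig) -> PairedOmics:
    """Generate paired RNA counts and protein intensities for every cell type.

    Returns matrices keyed by cell type and the complete planted-effect record.
    Deterministic: identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    cell_types = config.cell_types()

    perm = rng.permutation(config.n_genes)
    shared = [genes[i] for i in perm[: config.n_shared_signal]]
    specific: dict[str, list[str]] = {}
    offset = config.n_shared_signal
    for ct in cell_types:
        specific[ct] = [genes[i] for i in perm[offset: offset + config.n_specific_signal]]
        offset += config.n_specific_signal

    planted: dict[tuple[str, str, str], float] = {}
    for g in shared:
        e_rna, e_prot = _draw_effect_pair(rng, config)
        for ct in cell_types:
            planted[(g, ct, "rna")] = e_rna
            planted[(g, ct, "protein")] = e_prot
    for ct in cell_types:
        for g in specific[ct]:
            e_rna, e_prot = _draw_effect_pair(rng, config)
            planted[(g, ct, "rna")] = e_rna
            planted[(g, ct, "protein")] = e_prot

    # gene baselines: wide dynamic range shared across cell types, with a
    # cell-type identity component so samples cluster by cell type
    base_rel = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    base_prot = rng.normal(loc=20.0, scale=2.0, size=config.n_genes)  # log2 intensity
    dispersion = config.rna_dispersion * np.exp(rng.normal(0.0, 0.25, config.n_genes))

    half = (config.n_replicates + 1) // 2
    truth = SimTruth(
        shared_genes=set(shared),
        specific_genes={ct: set(s) for ct, s in specific.items()},
        planted_log2fc=planted,
    )
    # biopsy validation plants the upward-consistent shared genes
    truth.biopsy_shifted_genes = {
        g for g in shared if planted[(g, cell_types[0], "rna")] > 0
    }

    rna: dict[str, OmicsMatrix] = {}
    protein: dict[str, OmicsMatrix] = {}
    gene_index = {g: i for i, g in enumerate(genes)}

    for ct in cell_types:
        ct_jitter_rna = rng.normal(0.0, 0.4, config.n_genes)
        ct_jitter_prot = rng.normal(0.0, 0.5, config.n_genes)
        rel_ct = base_rel * np.exp2(ct_jitter_rna)
        frac = rel_ct / rel_ct.sum()

        metas: list[SampleMeta] = []
        rna_cols: list[np.ndarray] = []
        prot_cols: list[np.ndarray] = []
        for cond in ("basal", "insulin_resistant"):
            eff_rna = np.zeros(config.n_genes)
            eff_prot = np.zeros(config.n_genes)
            if cond == "insulin_resistant":
                for (g, c, layer), e in planted.items():
                    if c == ct:
                        idx = gene_index[g]
                        if layer == "rna":
                            eff_rna[idx] = e
                        else:
                            eff_prot[idx] = e
            for rep in range(1, config.n_replicates + 1):
                batch = "b1" if rep <= half else "b2"
                shift = config.batch_shift if batch == "b2" else 0.0
                lib = rng.uniform(*config.lib_size_range)
                mu = lib * frac * np.exp2(eff_rna + shift)
                shape = 1.0 / dispersion
                lam = rng.gamma(shape, mu * dispersion)
                counts = rng.poisson(lam)
                rna_cols.append(counts)
                log2_int = (
                    base_prot
                    + ct_jitter_prot
                    + eff_prot
                    + shift
                    + rng.normal(0.0, config.protein_cv, config.n_genes)
                )
                prot_cols.append(np.exp2(log2_int))
                metas.append(
                    SampleMeta(
                        sample_id=f"{ct}_{cond}_{rep}",
                        cell_type=ct,
                        condition=cond,
                        replicate=rep,
                        batch=batch,
                    )
                )
        ids = [m.sample_id for m in metas]
        rna[ct] = OmicsMatrix(
            pd.DataFrame(np.column_stack(rna_cols), index=genes, columns=ids),
            metas,
            "rna",
        )
        protein[ct] = OmicsMatrix(
            pd.DataFrame(np.column_stack(prot_cols), index=genes, columns=ids),
            metas,
            "protein",
        )

    return PairedOmics(rna=rna, protein=protein, truth=truth)


def simulate_ontology_and_sets(
    n_terms: int,
    genes: int | list[str],
    seed: int = 0,
    planted_genes: set[str] | None = None,
    n_planted_terms: int = 3,
    mean_direct_size: float = 6.0,
) -> tuple[Ontology, dict[str, set[str]], list[str]]:
    """Generate a rooted DAG of terms with gene annotations.

    Each term receives a direct gene set; annotations propagate to every
    ancestor, so a gene annotated to a child is annotated to the root.  When
    ``planted_genes`` is given, ``n_planted_terms`` late (leaf-side) terms are
    annotated predominantly with those genes, making them truly enriched.
    Returns (ontology, full gene sets, planted term ids).
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    if isinstance(genes, int):
        genes = [f"g{i:04d}" for i in range(genes)]
    genes = list(genes)

    onto = Ontology()
    ids = [f"T{i:04d}" for i in range(n_terms)]
    onto.add_term(ids[0], "root")
    for i in range(1, n_terms):
        onto.add_term(ids[i], f"term {i}")
        parent = ids[int(rng.integers(0, i))]
        onto.add_edge(ids[i], parent, "is_a")
        if i > 1 and rng.random() < 0.2:
            second = ids[int(rng.integers(0, i))]
            if second not in (parent, ids[i]):
                rel = "part_of" if rng.random() < 0.6 else "is_a"
                onto.add_edge(ids[i], second, rel)
    onto.validate()

    planted_terms: list[str] = []
    if planted_genes:
        pool = sorted(planted_genes)
        n_p = min(n_planted_terms, n_terms - 1)
        planted_terms = ids[n_terms - n_p:]

    direct: dict[str, set[str]] = {}
    for i, tid in enumerate(ids):
        size = max(1, int(rng.poisson(mean_direct_size)))
        if tid in planted_terms:
            pool = sorted(planted_genes)  # type: ignore[arg-type]
            k = min(len(pool), max(5, size))
            members = set(rng.choice(pool, size=k, replace=False))
            extra = rng.choice(genes, size=max(1, size // 3), replace=False)
            members |= set(extra)
        else:
            members = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        direct[tid] = {str(m) for m in members}

    full = annotations_with_ancestors(onto, direct)
    gene_sets = {t: full[t] for t in ids}
    return onto, gene_sets, planted_terms


@dataclass
class BiopsyConfig:
    """Parameters of the synthetic biopsy cohort (3 groups, log-scale chips)."""

    n_per_group: int = 20
    shift_log2: float = 1.0          # advanced-stage shift; early stage gets half
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 1.0
    phenotype_rho: dict[str, float] = field(
        default_factory=lambda: {"GFR": -0.6, "ACR": 0.5, "slope": -0.4}
    )


def simulate_biopsy_cohort(
    genes: list[str],
    truth: SimTruth,
    config: BiopsyConfig | None = None,
    seed: int = 0,
) -> BiopsyCohort:
    """Generate a 3-group biopsy-style cohort with planted pathway shifts.

    ``truth.biopsy_shifted_genes`` are elevated progressively
    (LD < early_DKD < advanced_DKD); phenotypes are generated with the
    configured Gaussian-copula correlation to the first shifted gene
    (independent standard noise otherwise), so Spearman links are recoverable.
    """
    cfg = config or BiopsyConfig()
    rng = np.random.default_rng(seed)
    n = 3 * cfg.n_per_group
    sample_ids = [f"s{i:03d}" for i in range(n)]
    groups = pd.Series(
        np.repeat(list(BIOPSY_GROUPS), cfg.n_per_group), index=sample_ids, name="group"
    )
    stage = groups.map({"LD": 0.0, "early_DKD": 0.5, "advanced_DKD": 1.0}).to_numpy()

    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    expr = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    shifted = sorted(truth.biopsy_shifted_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in shifted:
        if g in gidx:
            expr[gidx[g]] += cfg.shift_log2 * stage

    expression = pd.DataFrame(expr, index=list(genes), columns=sample_ids)

    anchor = next((g for g in shifted if g in gidx), genes[0])
    z = expression.loc[anchor].to_numpy()
    z = (z - z.mean()) / z.std()
    phen: dict[str, np.ndarray] = {}
    for name, rho in cfg.phenotype_rho.items():
        raw = rho * z + math.sqrt(max(0.0, 1 - rho * rho)) * rng.normal(0.0, 1.0, n)
        if name == "GFR":
            phen[name] = 90.0 + 25.0 * raw
        elif name == "ACR":
            phen[name] = np.exp2(5.0 + 2.0 * raw)
        else:
            phen[name] = raw
    phen["age"] = rng.normal(55.0, 10.0, n)
    phenotypes = pd.DataFrame(phen, index=sample_ids)

    return BiopsyCohort(expression=expression, groups=groups, phenotypes=phenotypes)
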