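"""Biopsy validation: Z-score pathway scoring, one-way ANOVA, SAM with an
exhaustive-permutation oracle, and Spearman phenotype correlation."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iromics.biopsy import (
    PathwayScoreTable,
    anova_groups,
    pathway_zscore,
    sam_two_class,
    spearman_phenotypes,
)
from iromics.datatypes import BiopsyCohort, SimTruth
from iromics.sim import BiopsyConfig, simulate_biopsy_cohort


def small_cohort(seed=0, n_genes=40, shift=1.0):
    genes = [f"g{i:04d}" for i in range(n_genes)]
    shifted = set(genes[:8])
    truth = SimTruth(
        shared_genes=shifted, specific_genes={}, planted_log2fc={},
        biopsy_shifted_genes=shifted,
    )
    cohort = simulate_biopsy_cohort(
        genes, truth, BiopsyConfig(n_per_group=10, shift_log2=shift), seed=seed
    )
    return cohort, shifted


class TestPathwayZscore:
    def test_single_gene_set_equals_that_genes_zscore(self):
        cohort, _ = small_cohort()
        gene = cohort.expression.index[0]
        tab = pathway_zscore(cohort, {gene})
        x = cohort.expression.loc[gene].to_numpy()
        z = (x - x.mean()) / x.std()
        assert np.allclose(tab.scores.to_numpy(), z, atol=1e-12)

    def test_cohort_mean_is_zero(self):
        cohort, shifted = small_cohort()
        tab = pathway_zscore(cohort, shifted)
        assert tab.scores.mean() == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_orders_group_means(self):
        cohort, shifted = small_cohort(shift=1.5)
        tab = pathway_zscore(cohort, shifted)
        means = tab.scores.groupby(cohort.groups).mean()
        assert means["advanced_DKD"] > means["LD"]

    def test_absent_genes_skipped_no_overlap_rejected(self):
        cohort, shifted = small_cohort()
        tab = pathway_zscore(cohort, shifted | {"missing"})
        assert "missing" not in tab.genes_used
        with pytest.raises(ValueError, match="overlap"):
            pathway_zscore(cohort, {"nope"})


class TestAnova:
    @staticmethod
    def _table(groups: dict[str, list[float]]) -> PathwayScoreTable:
        scores, labels = [], []
        for g, vals in groups.items():
            scores += vals
            labels += [g] * len(vals)
        idx = [f"s{i}" for i in range(len(scores))]
        return PathwayScoreTable(
            scores=pd.Series(scores, index=idx),
            groups=pd.Series(labels, index=idx),
            genes_used=["g"],
        )

    def test_hand_computed_f_and_p(self):
        # SSB = 13.5, SSW = 4, df = (1, 4) -> F = 13.5, p ~ 0.0213
        comp = anova_groups(self._table({"a": [1, 2, 3], "b": [4, 5, 6]}))
        assert comp.f_stat == pytest.approx(13.5)
        assert comp.p == pytest.approx(0.02131164, abs=1e-6)

    def test_identical_groups_f_zero(self):
        comp = anova_groups(self._table({"a": [1, 2, 3], "b": [1, 2, 3]}))
        assert comp.f_stat == pytest.approx(0.0)
        assert comp.p == pytest.approx(1.0)

    def test_location_invariance(self):
        a = anova_groups(self._table({"a": [1, 2, 3], "b": [2, 4, 6]}))
        b = anova_groups(self._table({"a": [11, 12, 13], "b": [12, 14, 16]}))
        assert a.f_stat == pytest.approx(b.f_stat, abs=1e-10)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_groups(self._table({"a": [1.0], "b": [2, 3]}))


def oracle_sam_q(expr: pd.DataFrame, groups: pd.Series, s0: float) -> np.ndarray:
    """Brute-force SAM q by full enumeration of group relabellings:
    per-gene median null exceedance count over observed count, monotone."""
    arr = expr.to_numpy(float)
    labels = groups.to_numpy()
    classes = sorted(set(labels))
    n = arr.shape[1]
    n1 = int((labels == classes[0]).sum())

    def d_stat(mask):
        a, b = arr[:, mask], arr[:, ~mask]
        m1, m2 = a.mean(1), b.mean(1)
        ss = ((a - m1[:, None]) ** 2).sum(1) + ((b - m2[:, None]) ** 2).sum(1)
        s = np.sqrt((1 / a.shape[1] + 1 / b.shape[1]) * ss / (n - 2))
        return (m1 - m2) / (s + s0)

    obs_mask = labels == classes[0]
    d_obs = d_stat(obs_mask)
    null_counts = []
    for combo in itertools.combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        d_null = np.abs(d_stat(mask))
        null_counts.append([(d_null >= t).sum() for t in np.abs(d_obs)])
    med = np.median(np.array(null_counts), axis=0)
    obs_counts = np.array([(np.abs(d_obs) >= t).sum() for t in np.abs(d_obs)])
    q = np.clip(med / obs_counts, 0, 1)
    order = np.argsort(-np.abs(d_obs), kind="mergesort")
    q_sorted = np.maximum.accumulate(q[order])
    out = np.empty_like(q_sorted)
    out[order] = q_sorted
    return out


class TestSam:
    @staticmethod
    def _fixture(seed=0, n_genes=30):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(6)]
        expr = pd.DataFrame(
            rng.normal(size=(n_genes, 6)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=cols,
        )
        expr.iloc[:5, 3:] += 2.0
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=cols)
        return expr, groups

    def test_s0_zero_preserves_t_ordering(self):
        expr, groups = self._fixture()
        res = sam_two_class(expr, groups, s0=0.0, exhaustive=True)
        t, _ = stats.ttest_ind(
            expr.loc[:, groups == "A"].T, expr.loc[:, groups == "B"].T, equal_var=True
        )
        order_d = np.argsort(-np.abs(res.table["d"].to_numpy()))
        order_t = np.argsort(-np.abs(t))
        assert list(order_d) == list(order_t)

    def test_exhaustive_q_matches_brute_force_oracle(self):
        expr, groups = self._fixture(seed=1)
        res = sam_two_class(expr, groups, exhaustive=True)
        expected = oracle_sam_q(expr, groups, res.s0)
        assert np.allclose(res.table["q"].to_numpy(), expected, atol=1e-12)
        assert res.n_perm == 20  # C(6,3) relabellings

    def test_null_data_q_large(self):
        rng = np.random.default_rng(3)
        cols = [f"s{i}" for i in range(12)]
        expr = pd.DataFrame(
            rng.normal(size=(200, 12)), index=[f"g{i}" for i in range(200)],
            columns=cols,
        )
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=cols)
        res = sam_two_class(expr, groups, n_perm=100, seed=0)
        assert res.table["q"].median() > 0.5

    def test_sign_agrees_with_moderated_t(self, small_paired):
        from iromics.diffexpr import fit_moderated_de
        from iromics.preprocess import normalize_protein

        nm = normalize_protein(small_paired.protein["Pod"])
        de = fit_moderated_de(nm)
        groups = pd.Series(
            nm.condition_labels(), index=nm.values.columns
        )
        res = sam_two_class(nm.values, groups, n_perm=20, seed=0)
        # classes sort alphabetically: basal minus insulin_resistant
        d = -res.table["d"].reindex(de.table.index)
        nz = de.table["log2fc"] != 0
        assert (np.sign(d[nz]) == np.sign(de.table["log2fc"][nz])).all()


class TestSpearman:
    @staticmethod
    def _cohort(expr_rows: dict[str, list[float]], phen: dict[str, list[float]]):
        n = len(next(iter(expr_rows.values())))
        idx = [f"s{i}" for i in range(n)]
        per_group = n // 3
        groups = pd.Series(
            ["LD"] * per_group
            + ["early_DKD"] * per_group
            + ["advanced_DKD"] * (n - 2 * per_group),
            index=idx,
        )
        return BiopsyCohort(
            expression=pd.DataFrame(expr_rows, index=idx).T,
            groups=groups,
            phenotypes=pd.DataFrame(phen, index=idx),
        )

    def test_perfect_monotone_rho_one(self):
        cohort = self._cohort(
            {"g1": list(range(1, 10))}, {"GFR": [10 * v for v in range(1, 10)]}
        )
        tab = spearman_phenotypes(cohort, ["g1"])
        assert tab.loc[0, "rho"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = list(rng.normal(size=9))
        y = list(rng.normal(size=9))
        a = spearman_phenotypes(
            self._cohort({"g1": x}, {"GFR": y}), ["g1"]
        ).loc[0, "rho"]
        b = spearman_phenotypes(
            self._cohort({"g1": x}, {"GFR": list(np.exp(y))}), ["g1"]
        ).loc[0, "rho"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_midrank_tie_fixture(self):
        # x = (1,2,2,3) midranks (1, 2.5, 2.5, 4); y = (1,2,3,4)
        x = [1.0, 2.0, 2.0, 3.0, 0.0, 5.0, 6.0, 7.0, 8.0]
        cohort = self._cohort({"g1": x[:4] + x[4:]}, {"GFR": list(range(9))})
        rx = stats.rankdata(x)
        ry = stats.rankdata(range(9))
        expected = np.corrcoef(rx, ry)[0, 1]
        tab = spearman_phenotypes(cohort, ["g1"])
        assert tab.loc[0, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_phenotype_reported_missing(self):
        cohort = self._cohort(
            {"g1": list(range(9))}, {"GFR": [5.0] * 9}
        )
        tab = spearman_phenotypes(cohort, ["g1"])
        assert np.isnan(tab.loc[0, "rho"])
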