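"""Rankings, preranked enrichment against a brute-force running-sum oracle,
hypergeometric over-representation, Wang similarity and term filtering."""
import math

import numpy as np
import pandas as pd
import pytest

from iromics.enrich import (
    RankedList,
    cluster_and_filter_terms,
    gsea_preranked,
    ora_hypergeometric,
    signal2noise_ranking,
    wang_similarity,
)
from iromics.ontology import Ontology

from conftest import make_normalized


def ranked(scores: dict[str, float]) -> RankedList:
    return RankedList(pd.Series(scores), "signal2noise")


def oracle_es(ranking: RankedList, members: set[str], weight: float = 1.0) -> float:
    """O(n) walk over the full ranked list, accumulating the weighted
    Kolmogorov-Smirnov running sum and returning its signed extreme."""
    ids = list(ranking.scores.index)
    scores = ranking.scores.to_numpy()
    hits = np.array([g in members for g in ids])
    n_miss = len(ids) - hits.sum()
    w = np.abs(scores) ** weight
    total = w[hits].sum()
    if total == 0:
        w = np.ones_like(w)
        total = float(hits.sum())
    running, best = 0.0, 0.0
    for i in range(len(ids)):
        if hits[i]:
            running += w[i] / total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestSignal2Noise:
    def test_direct_formula(self):
        rng = np.random.default_rng(0)
        # group means 2 vs 1 with sds 0.5: score (2-1)/(0.5+0.5) = 1
        b = np.array([1.5, 0.5, 1.0, 1.5, 0.5])
        ir = b + 1.0
        vals = np.concatenate([b, ir])[None, :].repeat(2, axis=0)
        vals[1] = np.concatenate([b, b])  # equal means -> 0
        nm = make_normalized(vals)
        rl = signal2noise_ranking(nm)
        sd = np.std(b, ddof=1)
        assert rl.scores["g000"] == pytest.approx(1.0 / (2 * sd))
        assert rl.scores["g001"] == pytest.approx(0.0)

    def test_label_flip_negates_scores(self, small_paired):
        from iromics.preprocess import normalize_protein

        nm = normalize_protein(small_paired.protein["Pod"])
        a = signal2noise_ranking(nm).scores
        flipped = np.where(
            nm.condition_labels() == "basal", "insulin_resistant", "basal"
        )
        b = signal2noise_ranking(nm, groups=flipped).scores
        assert np.allclose(a.sort_index(), -b.sort_index(), atol=1e-12)

    def test_small_group_rejected(self):
        nm = make_normalized(np.ones((3, 2)), n_per_cond=1)
        with pytest.raises(ValueError, match="2 samples"):
            signal2noise_ranking(nm)


class TestGseaEs:
    def test_top_ranked_single_member_es_one(self):
        rl = ranked({f"g{i}": 10.0 - i for i in range(10)})
        df = gsea_preranked(rl, {"s": {"g0"}}, min_size=1, n_perm=50, seed=0)
        assert df.loc["s", "es"] == pytest.approx(1.0)
        assert df.loc["s", "leading_edge"] == "g0"

    def test_bottom_ranked_single_member_es_minus_one(self):
        rl = ranked({f"g{i}": 10.0 - i for i in range(10)})
        df = gsea_preranked(rl, {"s": {"g9"}}, min_size=1, n_perm=50, seed=0)
        # nine misses of -1/9 then the hit: extreme is -1 just before it
        assert df.loc["s", "es"] == pytest.approx(-1.0)
        assert df.loc["s", "leading_edge"] == "g9"

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            n = int(rng.integers(20, 120))
            ids = [f"g{i}" for i in range(n)]
            rl = RankedList(pd.Series(rng.normal(size=n), index=ids), "signal2noise")
            m = int(rng.integers(2, max(3, n // 4)))
            members = set(rng.choice(ids, size=m, replace=False))
            df = gsea_preranked(
                rl, {"s": members}, min_size=1, n_perm=10, seed=trial
            )
            assert df.loc["s", "es"] == pytest.approx(
                oracle_es(rl, members), abs=1e-12
            )

    def test_weight_zero_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(50)]
        scores = pd.Series(np.sort(rng.normal(size=50))[::-1], index=ids)
        members = set(rng.choice(ids, size=8, replace=False))
        a = gsea_preranked(
            RankedList(scores, "signal2noise"), {"s": members}, weight=0.0,
            min_size=1, n_perm=10, seed=0,
        ).loc["s", "es"]
        b = gsea_preranked(
            RankedList(np.exp(scores) + 5, "signal2noise"), {"s": members},
            weight=0.0, min_size=1, n_perm=10, seed=0,
        ).loc["s", "es"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_planted_set_detected_null_sets_not(self):
        rng = np.random.default_rng(5)
        n = 500
        ids = [f"g{i}" for i in range(n)]
        scores = rng.normal(size=n)
        scores[:25] += 2.5
        rl = RankedList(pd.Series(scores, index=ids), "signal2noise")
        sets = {"planted": set(ids[:25])}
        for j in range(10):
            sets[f"null{j}"] = set(rng.choice(ids, size=25, replace=False))
        df = gsea_preranked(rl, sets, n_perm=500, seed=0)
        assert df.loc["planted", "nes"] > 0
        assert df.loc["planted", "q"] < 0.1
        assert (df.drop(index="planted")["p"] > 0.01).all()


class TestOra:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(5)}
        p, fold, overlap = ora_hypergeometric(target, target, universe)
        assert p == pytest.approx(1.0 / math.comb(20, 5), rel=1e-12)
        assert overlap == 5 and fold == pytest.approx(4.0)

    def test_selected_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        target = {f"g{i}" for i in range(7)}
        p, _, _ = ora_hypergeometric(universe, target, universe)
        assert p == pytest.approx(1.0)

    def test_zero_overlap_matches_closed_form_sum(self):
        universe = {f"g{i}" for i in range(12)}
        selected = {f"g{i}" for i in range(4)}
        target = {f"g{i}" for i in range(8, 12)}
        p, _, overlap = ora_hypergeometric(selected, target, universe)
        assert overlap == 0
        # P(X >= 0) = 1 by definition of the upper tail
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeometric({"a"}, {"a"}, set())


def chain_ontology() -> Ontology:
    onto = Ontology()
    for t in ("R", "A", "B"):
        onto.add_term(t)
    onto.add_edge("A", "R", "is_a")
    onto.add_edge("B", "A", "part_of")
    return onto


class TestWang:
    def test_self_similarity_one(self):
        onto = chain_ontology()
        for t in ("R", "A", "B"):
            assert wang_similarity(t, t, onto) == pytest.approx(1.0)

    def test_hand_computed_root_child_value(self):
        onto = Ontology()
        onto.add_term("R")
        onto.add_term("A")
        onto.add_edge("A", "R", "is_a")
        # S_A = {A:1, R:0.8}, SV(A)=1.8, SV(R)=1, common={R}
        assert wang_similarity("A", "R", onto) == pytest.approx((0.8 + 1) / 2.8)

    def test_part_of_chain_svalues(self):
        onto = chain_ontology()
        # S_B = {B:1, A:0.6, R:0.48}; S_A = {A:1, R:0.8}
        sv = onto.svalues("B")
        assert sv == pytest.approx({"B": 1.0, "A": 0.6, "R": 0.48})
        expected = (0.6 + 1 + 0.48 + 0.8) / ((1 + 0.6 + 0.48) + (1 + 0.8))
        assert wang_similarity("B", "A", onto) == pytest.approx(expected)

    def test_symmetry_on_random_ontology(self):
        from iromics.sim import simulate_ontology_and_sets

        onto, _, _ = simulate_ontology_and_sets(25, 50, seed=11)
        rng = np.random.default_rng(0)
        terms = onto.terms
        for _ in range(10):
            a, b = rng.choice(terms, size=2, replace=False)
            assert wang_similarity(a, b, onto) == pytest.approx(
                wang_similarity(b, a, onto), abs=1e-12
            )

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            wang_similarity("A", "nope", chain_ontology())


class TestTermFilter:
    @staticmethod
    def _result(p, q, nes=1.5):
        return pd.DataFrame(
            {"es": nes / 2, "nes": nes, "p": p, "q": q, "leading_edge": "g1"},
            index=["T"],
        )

    def test_both_layers_one_cell_type_retained(self):
        onto = chain_ontology()
        onto.add_term("T")
        onto.add_edge("T", "R", "is_a")
        results = {
            ("Pod", "rna", "signal2noise"): self._result(0.01, 0.05),
            ("Pod", "protein", "signal2noise"): self._result(0.02, 0.08),
            ("GEC", "rna", "signal2noise"): self._result(0.5, 0.9),
            ("GEC", "protein", "signal2noise"): self._result(0.5, 0.9),
        }
        nes, clusters, _ = cluster_and_filter_terms(results, onto)
        assert list(nes.index) == ["T"]

    def test_single_layer_everywhere_dropped(self):
        onto = chain_ontology()
        onto.add_term("T")
        onto.add_edge("T", "R", "is_a")
        results = {
            ("Pod", "rna", "signal2noise"): self._result(0.01, 0.05),
            ("Pod", "protein", "signal2noise"): self._result(0.5, 0.9),
            ("GEC", "rna", "signal2noise"): self._result(0.01, 0.05),
            ("GEC", "protein", "signal2noise"): self._result(0.5, 0.9),
        }
        nes, clusters, _ = cluster_and_filter_terms(results, onto)
        assert len(nes) == 0

    def test_either_ranking_kind_counts(self):
        onto = chain_ontology()
        onto.add_term("T")
        onto.add_edge("T", "R", "is_a")
        results = {
            ("Pod", "rna", "signal2noise"): self._result(0.5, 0.9),
            ("Pod", "rna", "opls_loading"): self._result(0.01, 0.05),
            ("Pod", "protein", "signal2noise"): self._result(0.02, 0.08),
            ("Pod", "protein", "opls_loading"): self._result(0.5, 0.9),
        }
        nes, _, _ = cluster_and_filter_terms(results, onto)
        assert list(nes.index) == ["T"]

    def test_identical_ancestry_terms_share_cluster(self):
        onto = Ontology()
        onto.add_term("R")
        for t in ("X", "Y", "Z"):
            onto.add_term(t)
            onto.add_edge(t, "R", "is_a")
        results = {}
        for term in ("X", "Y"):
            for layer in ("rna", "protein"):
                df = pd.DataFrame(
                    {"es": 0.5, "nes": 1.5, "p": 0.01, "q": 0.05, "leading_edge": "g"},
                    index=["X", "Y"],
                )
                results[("Pod", layer, "signal2noise")] = df
        # X and Y hang off the root identically: sim = (0.8+0.8)/(1.8+1.8)
        assert wang_similarity("X", "Y", onto) == pytest.approx(4 / 9)
        # clustering at a cut above their distance (1 - 4/9) merges them
        nes, clusters, _ = cluster_and_filter_terms(results, onto, cut_distance=0.6)
        assert clusters["X"] == clusters["Y"]
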