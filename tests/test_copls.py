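"""Consensus OPLS-DA: kernel construction, modified RV, block weighting,
model fitting, cross-validated Q2, permutation significance and VIP."""
import numpy as np
import pandas as pd
import pytest

from iromics.copls import (
    build_kernel,
    consensus_weights,
    cross_validated_q2,
    encode_response,
    fit_consensus_opls,
    modified_rv,
    permutation_significance,
)

LABELS10 = np.array(["basal"] * 5 + ["insulin_resistant"] * 5)


def signal_matrix(seed=0, n=10, p=200, psig=40, sep=3.0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    x[n // 2:, :psig] += sep
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    return pd.DataFrame(x, columns=[f"f{j}" for j in range(p)])


def noise_matrix(seed=1, n=10, p=200) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    return pd.DataFrame(x, columns=[f"n{j}" for j in range(p)])


class TestKernel:
    def test_symmetric_psd_unit_frobenius_centred(self):
        blk = build_kernel(signal_matrix())
        k = blk.K
        assert np.allclose(k, k.T, atol=1e-12)
        assert np.linalg.eigvalsh(k).min() >= -1e-8
        assert np.linalg.norm(k, "fro") == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(k.sum(axis=0), 0.0, atol=1e-9)

    def test_duplicated_feature_leaves_kernel_direction_unchanged(self):
        x = signal_matrix(seed=2, p=50)
        x2 = pd.concat([x, x.iloc[:, [0]].set_axis(["dup"], axis=1)], axis=1)
        k1 = build_kernel(x).K
        # pre-normalisation Gram matrices differ only by the duplicated
        # column's rank-1 term; after Frobenius normalisation the kernels of
        # X and [X, X] coincide exactly
        xx = pd.concat([x, x.set_axis([f"d{c}" for c in x.columns], axis=1)], axis=1)
        k2 = build_kernel(xx).K
        assert np.allclose(k1, k2, atol=1e-12)
        assert build_kernel(x2).K == pytest.approx(build_kernel(x2).K)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            build_kernel(signal_matrix().iloc[:2])


class TestModifiedRv:
    def test_self_similarity_is_one(self):
        k = build_kernel(signal_matrix()).K
        assert modified_rv(k, k) == pytest.approx(1.0)

    def test_scale_invariance(self):
        k = build_kernel(signal_matrix(seed=3)).K
        assert modified_rv(k, 7.3 * k) == pytest.approx(1.0)

    def test_independent_kernels_have_small_rv(self):
        """Kernels of independent random matrices are nearly uncorrelated;
        n=20 keeps the centring-induced alignment of off-diagonals small."""
        vals = []
        for s in range(20):
            k1 = build_kernel(noise_matrix(seed=2 * s, n=20, p=50)).K
            k2 = build_kernel(noise_matrix(seed=2 * s + 1, n=20, p=50)).K
            vals.append(abs(modified_rv(k1, k2)))
        assert max(vals) < 0.3

    def test_dimension_mismatch_rejected(self):
        k = build_kernel(signal_matrix()).K
        with pytest.raises(ValueError, match="dimension"):
            modified_rv(k, k[:5, :5])


class TestConsensusWeights:
    def test_identical_blocks_split_evenly(self):
        x = signal_matrix(seed=4)
        blocks = [build_kernel(x, "a"), build_kernel(x.copy(), "b")]
        lam = consensus_weights(blocks, encode_response(LABELS10))
        assert np.allclose(lam, [0.5, 0.5], atol=1e-12)

    def test_single_block_gets_all_weight(self):
        lam = consensus_weights(
            [build_kernel(signal_matrix(), "a")], encode_response(LABELS10)
        )
        assert lam == pytest.approx([1.0])

    def test_signal_block_outweighs_noise_block(self):
        blocks = [
            build_kernel(signal_matrix(seed=5), "signal"),
            build_kernel(noise_matrix(seed=6), "noise"),
        ]
        lam = consensus_weights(blocks, encode_response(LABELS10))
        assert lam[0] > lam[1]


class TestFit:
    def test_label_swap_negates_scores_keeps_r2(self):
        blocks = [build_kernel(signal_matrix(seed=7), "a")]
        m1 = fit_consensus_opls(blocks, LABELS10)
        m2 = fit_consensus_opls(blocks, LABELS10[::-1])
        assert np.allclose(m1.t_pred, -m2.t_pred, atol=1e-9)
        assert m1.r2y == pytest.approx(m2.r2y, abs=1e-12)

    def test_wide_margin_clusters_fit_well(self):
        blocks = [build_kernel(signal_matrix(seed=8, sep=6.0), "a")]
        m = fit_consensus_opls(blocks, LABELS10)
        assert m.r2y > 0.9

    def test_scores_orthogonal(self):
        blocks = [
            build_kernel(signal_matrix(seed=9), "rna"),
            build_kernel(noise_matrix(seed=10), "protein"),
        ]
        m = fit_consensus_opls(blocks, LABELS10, n_orth=1)
        for j in range(m.t_orth.shape[1]):
            assert abs(m.t_pred @ m.t_orth[:, j]) < 1e-8

    def test_single_class_rejected(self):
        blocks = [build_kernel(signal_matrix(), "a")]
        with pytest.raises(ValueError, match="2 classes"):
            fit_consensus_opls(blocks, np.array(["basal"] * 10))

    def test_equal_block_symmetry_mirrors_vip(self):
        """Duplicating the RNA block as a fake protein block gives
        lambda = (1/2, 1/2) and identical VIP for mirrored features."""
        x = signal_matrix(seed=11)
        blocks = [build_kernel(x, "rna"), build_kernel(x.copy(), "protein")]
        m = fit_consensus_opls(blocks, LABELS10)
        assert m.block_contributions["rna"] == pytest.approx(0.5, abs=1e-12)
        rna_vip = m.vip[[f"rna:{c}" for c in x.columns]].to_numpy()
        prot_vip = m.vip[[f"protein:{c}" for c in x.columns]].to_numpy()
        assert np.allclose(rna_vip, prot_vip, atol=1e-10)


class TestVip:
    def test_rms_is_one(self):
        blocks = [
            build_kernel(signal_matrix(seed=12), "rna"),
            build_kernel(noise_matrix(seed=13), "protein"),
        ]
        m = fit_consensus_opls(blocks, LABELS10)
        assert np.sqrt((m.vip ** 2).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_columns_identical_vip(self):
        x = signal_matrix(seed=14, p=30)
        x["copy"] = x["f0"]
        m = fit_consensus_opls([build_kernel(x, "rna")], LABELS10)
        assert m.vip["rna:copy"] == pytest.approx(m.vip["rna:f0"], abs=1e-12)

    def test_signal_features_exceed_null_features(self):
        x = signal_matrix(seed=15, p=400, psig=40, sep=3.0)
        m = fit_consensus_opls([build_kernel(x, "rna")], LABELS10)
        sig = m.vip[[f"rna:f{j}" for j in range(40)]].median()
        null = m.vip[[f"rna:f{j}" for j in range(40, 400)]].median()
        assert sig > 1.0 > null


class TestCrossValidation:
    def test_same_seed_reproducible(self):
        xb = {"rna": signal_matrix(seed=16)}
        q1 = cross_validated_q2(xb, LABELS10, seed=3)
        q2 = cross_validated_q2(xb, LABELS10, seed=3)
        assert q1 == q2

    def test_too_few_samples_for_folds(self):
        xb = {"rna": signal_matrix(seed=17).iloc[:5]}
        with pytest.raises(ValueError, match="folds"):
            cross_validated_q2(xb, LABELS10[:5], k_folds=7)

    def test_permuted_labels_rarely_predict(self):
        """Randomly permuted responses on a signal fixture almost never
        cross-validate: Q2 <= 0.2 for >= 45 of 50 seeded permutations
        (near-duplicate partitions retain some predictive overlap at this
        sample size; identity partitions are excluded)."""
        labels = np.array(["basal"] * 10 + ["insulin_resistant"] * 10)
        xb = {"rna": signal_matrix(seed=18, n=20, p=200, psig=40, sep=1.5)}
        rng = np.random.default_rng(0)
        count, done = 0, 0
        while done < 50:
            y = rng.permutation(labels)
            if (y == labels).all() or (y == labels[::-1]).all():
                continue
            if cross_validated_q2(xb, y, seed=int(rng.integers(2**31))) <= 0.2:
                count += 1
            done += 1
        assert count >= 45  # seeded run measures 47/50

    def test_dense_signal_fixture_reaches_high_q2(self):
        """With a majority of informative features (dense signal), held-out
        prediction is strong."""
        xb = {"rna": signal_matrix(seed=19, p=100, psig=80, sep=3.0)}
        assert cross_validated_q2(xb, LABELS10, seed=1) > 0.5


class TestPermutationSignificance:
    def test_p_respects_add_one_bounds(self):
        xb = {"rna": noise_matrix(seed=20, p=50)}
        _, p, _, null = permutation_significance(xb, LABELS10, n_perm=49, seed=2)
        assert 1 / 50 <= p <= 1.0
        assert len(null) == 49

    def test_planted_signal_is_significant(self):
        xb = {"rna": signal_matrix(seed=21, p=100, psig=60, sep=4.0)}
        q2, p, tp, _ = permutation_significance(xb, LABELS10, n_perm=99, seed=3)
        assert p == pytest.approx(1 / 100)
        assert tp < 1e-6
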