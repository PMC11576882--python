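"""Two-block consensus OPLS-DA: kernels, modified-RV block weighting,
orthogonal-projection fitting, cross-validated Q2, permutation significance
and variable importance in projection (VIP).

Each omics block contributes a linear sample-by-sample kernel K_b = X_b X_b^T
(double-centred, unit Frobenius norm).  The consensus kernel is the
RV-weighted sum  K = sum_b lambda_b K_b  with  lambda_b proportional to the
modified RV coefficient between K_b and the response kernel y y^T.  Because
the kernels are linear, the consensus kernel is exactly the Gram matrix of
the horizontally concatenated, block-scaled data, so the model is fitted in
that feature space (orthogonal components deflate the data before the final
predictive fit); scores, R2/Q2 and back-projected loadings are identical to
the kernel-space formulation while held-out samples project directly.

The model separates predictive variation (one component for a two-class
response) from response-orthogonal variation, giving interpretable scores:
t_pred discriminates basal from insulin-resistant samples, t_orth captures
structured variation unrelated to the contrast.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NormalizedMatrix
from .preprocess import autoscale


@dataclass
class KernelBlock:
    """One block's autoscaled data and its normalised linear kernel."""

    name: str
    X: pd.DataFrame          # samples x features, as supplied (autoscaled)
    col_mean: np.ndarray     # per-feature centring applied before the kernel
    scale: float             # 1/sqrt(frobenius norm of the centred kernel)
    Xs: np.ndarray           # centred, scaled data: Xs @ Xs.T == K
    K: np.ndarray            # double-centred, unit-Frobenius kernel
    weight: float = np.nan

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Project new sample rows into the block's scaled feature space."""
        return (np.asarray(X_new, dtype=float) - self.col_mean) * self.scale


def build_kernel(X: pd.DataFrame, name: str = "block") -> KernelBlock:
    """Linear kernel XX^T of a sample-by-feature matrix, double-centred and
    scaled to unit Frobenius norm."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("kernel needs at least 3 samples")
    if np.isnan(arr).any():
        raise ValueError("missing values not allowed")
    col_mean = arr.mean(axis=0)
    xc = arr - col_mean
    k = xc @ xc.T
    fro = float(np.linalg.norm(k, "fro"))
    if fro == 0:
        raise ValueError("degenerate block: zero kernel")
    scale = 1.0 / np.sqrt(fro)
    xs = xc * scale
    return KernelBlock(
        name=name, X=X, col_mean=col_mean, scale=scale, Xs=xs, K=k / fro
    )


def modified_rv(k1: np.ndarray, k2: np.ndarray) -> float:
    """Matrix correlation of two sample-similarity matrices with diagonals
    removed (reduces the size bias of the plain RV coefficient)."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if k1.shape != k2.shape or k1.shape[0] != k1.shape[1]:
        raise ValueError("kernels must be square and of equal dimension")
    a = k1 - np.diag(np.diag(k1))
    b = k2 - np.diag(np.diag(k2))
    denom = np.linalg.norm(a, "fro") * np.linalg.norm(b, "fro")
    if denom == 0:
        raise ValueError("degenerate kernel with zero off-diagonal norm")
    return float(np.sum(a * b) / denom)


def encode_response(y) -> np.ndarray:
    """Centred +/-1 two-class indicator."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"response must have exactly 2 classes, got {list(classes)}")
    z = np.where(y == classes[1], 1.0, -1.0)
    return z - z.mean()


def consensus_weights(blocks: list[KernelBlock], y_enc: np.ndarray) -> np.ndarray:
    """Block weights proportional to modified RV against the response kernel,
    clipped at zero and normalised to sum 1."""
    ky = np.outer(y_enc, y_enc)
    rv = np.array([max(modified_rv(b.K, ky), 0.0) for b in blocks])
    if rv.sum() == 0:
        raise ValueError("no block relates to the response")
    return rv / rv.sum()


@dataclass
class ConsensusModel:
    t_pred: np.ndarray
    t_orth: np.ndarray               # n x n_orth
    r2y: float
    block_contributions: dict[str, float]
    block_rv_pred: dict[str, float]  # modified RV of each block vs t_pred kernel
    loadings: pd.Series              # (block:feature) -> p_b = X_b^T t / (t^T t)
    vip: pd.Series                   # RMS-normalised, same index
    b_coef: float
    y_mean: float
    weights_pred: np.ndarray = field(repr=False, default=None)
    orth_w: list[np.ndarray] = field(repr=False, default_factory=list)
    orth_p: list[np.ndarray] = field(repr=False, default_factory=list)
    lambdas: np.ndarray = field(repr=False, default=None)
    q2: float = np.nan
    perm_p: float = np.nan
    perm_t_p: float = np.nan
    null_q2: np.ndarray = field(repr=False, default=None)


def _opls_fit(xt: np.ndarray, y: np.ndarray, n_orth: int):
    """Primal OPLS on concatenated scaled data: returns predictive weight,
    score, orthogonal weights/loadings/scores after deflation."""
    xd = xt.copy()
    orth_w, orth_p, orth_t = [], [], []
    for _ in range(n_orth):
        w = xd.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p = xd.T @ t / tt
        w_o = p - float(w @ p) * w
        nwo = np.linalg.norm(w_o)
        if nwo < 1e-12:
            break  # no response-orthogonal structure left
        w_o = w_o / nwo
        t_o = xd @ w_o
        tto = float(t_o @ t_o)
        p_o = xd.T @ t_o / tto
        xd = xd - np.outer(t_o, p_o)
        orth_w.append(w_o)
        orth_p.append(p_o)
        orth_t.append(t_o)
    w = xd.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response has no covariance with the data")
    w = w / nw
    t_pred = xd @ w
    return w, t_pred, orth_w, orth_p, orth_t


def fit_consensus_opls(
    blocks: list[KernelBlock],
    y,
    n_pred: int = 1,
    n_orth: int = 1,
    lambdas: np.ndarray | None = None,
) -> ConsensusModel:
    """Fit the consensus OPLS-DA model (1 predictive + n_orth orthogonal
    latent variables) on weighted blocks."""
    if n_pred != 1:
        raise ValueError("a two-class response supports exactly 1 predictive component")
    y_enc = encode_response(y)
    if lambdas is None:
        lambdas = consensus_weights(blocks, y_enc)
    xt = np.hstack([np.sqrt(lam) * b.Xs for b, lam in zip(blocks, lambdas)])
    w, t_pred, orth_w, orth_p, orth_t = _opls_fit(xt, y_enc, n_orth)

    tt = float(t_pred @ t_pred)
    b_coef = float(t_pred @ y_enc) / tt
    resid = y_enc - b_coef * t_pred
    tss = float(y_enc @ y_enc)
    r2y = 1.0 - float(resid @ resid) / tss

    kt = np.outer(t_pred, t_pred)
    block_rv = {blk.name: modified_rv(blk.K, kt) for blk in blocks}

    idx, load = [], []
    for blk in blocks:
        xb = blk.X.to_numpy(dtype=float)
        xb = xb - xb.mean(axis=0)
        p_b = xb.T @ t_pred / tt
        idx += [f"{blk.name}:{f}" for f in blk.X.columns]
        load.append(p_b)
    loadings = pd.Series(np.concatenate(load), index=idx, name="loading")
    vip = compute_vip(loadings)

    t_orth = np.column_stack(orth_t) if orth_t else np.zeros((len(y_enc), 0))
    raw = np.asarray(y)
    classes = np.unique(raw)
    z = np.where(raw == classes[1], 1.0, -1.0)
    return ConsensusModel(
        t_pred=t_pred,
        t_orth=t_orth,
        r2y=r2y,
        block_contributions={blk.name: float(lam) for blk, lam in zip(blocks, lambdas)},
        block_rv_pred=block_rv,
        loadings=loadings,
        vip=vip,
        b_coef=b_coef,
        y_mean=float(z.mean()),
        weights_pred=w,
        orth_w=orth_w,
        orth_p=orth_p,
        lambdas=np.asarray(lambdas, dtype=float),
    )


def compute_vip(loadings: pd.Series) -> pd.Series:
    """VIP over concatenated blocks for a single predictive component.

    With one component the SSY weighting collapses and
    VIP_j = sqrt(P) * |w_j| / ||w||, so the root-mean-square VIP is exactly 1;
    VIP > 1 marks above-average contribution to the discrimination.
    """
    w = loadings.to_numpy(dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("all-zero loadings")
    vip = np.sqrt(len(w)) * np.abs(w) / norm
    return pd.Series(vip, index=loadings.index, name="vip")


def _predict(
    model_w: np.ndarray,
    orth_w: list[np.ndarray],
    orth_p: list[np.ndarray],
    xt_new: np.ndarray,
) -> np.ndarray:
    xd = xt_new.copy()
    for w_o, p_o in zip(orth_w, orth_p):
        t_o = xd @ w_o
        xd = xd - np.outer(t_o, p_o)
    return xd @ model_w


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    classes = np.unique(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in classes:
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.array(sorted(f), dtype=int) for f in folds if len(f) > 0]


def cross_validated_q2(
    x_blocks: dict[str, pd.DataFrame],
    y,
    k_folds: int = 7,
    seed: int | np.random.Generator = 0,
    n_orth: int = 1,
) -> float:
    """Q2 = 1 - PRESS/TSS from stratified k-fold cross-validation.

    Block kernels, consensus weights and the model are all refitted on each
    training fold; held-out samples are projected with the training-fold
    centring and scaling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y)
    n = len(y)
    if n < k_folds:
        raise ValueError(f"n={n} samples cannot fill {k_folds} folds; lower k_folds")
    names = list(x_blocks)
    mats = {m: x_blocks[m].to_numpy(dtype=float) for m in names}
    classes = np.unique(y)
    z_all = np.where(y == classes[1], 1.0, -1.0)
    folds = _stratified_folds(y, k_folds, rng)
    press = 0.0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        blocks = [
            build_kernel(
                pd.DataFrame(mats[m][train_idx], columns=x_blocks[m].columns), name=m
            )
            for m in names
        ]
        z_train = z_all[train_idx]
        y_enc = z_train - z_train.mean()
        try:
            lambdas = consensus_weights(blocks, y_enc)
        except ValueError:
            # no block shows positive RV with this (e.g. permuted) response;
            # fall back to equal weights and let the fold predict poorly
            lambdas = np.full(len(blocks), 1.0 / len(blocks))
        xt = np.hstack([np.sqrt(lam) * b.Xs for b, lam in zip(blocks, lambdas)])
        w, t_pred, orth_w, orth_p, _ = _opls_fit(xt, y_enc, n_orth)
        tt = float(t_pred @ t_pred)
        b_coef = float(t_pred @ y_enc) / tt
        xt_new = np.hstack(
            [
                np.sqrt(lam) * b.transform(mats[m][test_idx])
                for b, lam, m in zip(blocks, lambdas, names)
            ]
        )
        t_new = _predict(w, orth_w, orth_p, xt_new)
        yhat = z_train.mean() + b_coef * t_new
        press += float(np.sum((z_all[test_idx] - yhat) ** 2))
    z_c = z_all - z_all.mean()
    tss = float(z_c @ z_c)
    return 1.0 - press / tss


def permutation_significance(
    x_blocks: dict[str, pd.DataFrame],
    y,
    n_perm: int = 1000,
    seed: int = 0,
    k_folds: int = 7,
    n_orth: int = 1,
) -> tuple[float, float, float, np.ndarray]:
    """Permutation test of the cross-validated Q2.

    Returns (q2_observed, perm_p, perm_t_p, null Q2 sample) with the add-one
    estimator  perm_p = (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1)  and a
    one-sample t-test of the null distribution against the observed Q2.
    """
    import warnings

    if n_perm < 20:
        warnings.warn("n_perm < 20 gives a very coarse permutation p-value")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    q2_obs = cross_validated_q2(x_blocks, y, k_folds, rng, n_orth)
    classes = np.unique(y)
    flipped = np.where(y == classes[0], classes[1], classes[0])
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        # with n this small a random permutation reproduces the observed
        # partition with non-negligible probability; the null is over
        # relabellings distinct from the observed assignment
        tries = 0
        while (
            np.array_equal(y_perm, y) or np.array_equal(y_perm, flipped)
        ) and tries < 100:
            y_perm = rng.permutation(y)
            tries += 1
        try:
            null[i] = cross_validated_q2(x_blocks, y_perm, k_folds, rng, n_orth)
        except ValueError:  # permutation with no response-related block
            null[i] = -np.inf
    finite_null = null[np.isfinite(null)]
    perm_p = (1.0 + float(np.sum(null >= q2_obs))) / (n_perm + 1.0)
    t_res = stats.ttest_1samp(finite_null, q2_obs)
    return q2_obs, perm_p, float(t_res.pvalue), null


def consensus_opls_da(
    rna: NormalizedMatrix,
    protein: NormalizedMatrix,
    n_orth: int = 1,
    k_folds: int = 7,
    n_perm: int = 1000,
    seed: int = 0,
) -> ConsensusModel:
    """End-to-end per-cell-type model: autoscale both layers, weight blocks,
    fit, cross-validate and permutation-test."""
    conds = rna.condition_labels()
    if not np.array_equal(conds, protein.condition_labels()):
        raise ValueError("RNA and protein samples must be aligned")
    scaled = {}
    for name, mat in (("rna", rna), ("protein", protein)):
        s, _ = autoscale(mat)
        scaled[name] = s.T  # samples x features
    blocks = [build_kernel(scaled[m], name=m) for m in ("rna", "protein")]
    model = fit_consensus_opls(blocks, conds, n_orth=n_orth)
    q2, perm_p, perm_t_p, null = permutation_significance(
        scaled, conds, n_perm=n_perm, seed=seed, k_folds=k_folds, n_orth=n_orth
    )
    model.q2 = q2
    model.perm_p = perm_p
    model.perm_t_p = perm_t_p
    model.null_q2 = null
    return model
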