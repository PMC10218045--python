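"""Latent-component extraction for sparse multi-block PLS-DA.

The model constructs orthogonal PLS components maximising the covariance
between a predictor summary (the super score ``t_super``, a weighted
combination of per-block scores) and an outcome summary ``u = Y q``, under
unit-norm weight constraints. Sparsity is imposed per block by
soft-thresholding the block weight at a quantile of its absolute entries, so
the retained fraction of features is roughly ``1 - quantile``.

All functions here operate on plain lists of numpy arrays; the estimator in
:mod:`asmbplsda.estimator` is the user-facing surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PreprocessState:
    """Weighted-centring offsets and scales, stored for prediction.

    Offsets are the average of the per-group feature means (not the grand
    mean), so unequal group sizes do not shift the decision boundary toward
    the larger group. X is centred and scaled; Y is only centred.
    """

    x_offsets: list[np.ndarray]
    x_scales: list[np.ndarray]
    y_offsets: np.ndarray


@dataclass
class ComponentFit:
    """Weights and loadings of one fitted PLS component."""

    block_weights: list[np.ndarray]       # unit-norm sparse omega_jb
    super_weight: np.ndarray              # unit-norm omega_super, length B
    q: np.ndarray                         # unit-norm outcome weight
    quantiles_used: np.ndarray
    t_super: np.ndarray | None = None     # training super score
    block_loadings: list[np.ndarray] = field(default_factory=list)  # p_jb
    y_loading: np.ndarray | None = None   # regression of Y on t_super
    n_iter: int = 0

    @property
    def support(self) -> list[np.ndarray]:
        """Indices of non-zero block weights (the selected features)."""
        return [np.flatnonzero(w) for w in self.block_weights]


def group_mean_offsets(M: np.ndarray, labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Average of per-group column means: the weighted-centring offset."""
    means = np.stack([M[labels == c].mean(axis=0) for c in classes])
    return means.mean(axis=0)


def weighted_center_scale(blocks, Y, labels, classes):
    """Weighted-centre and scale X blocks; weighted-centre Y.

    Each X column has the average of its per-group means subtracted (for two
    groups ``(mean_A + mean_B)/2``, for G groups the G-way average), then is
    divided by its sample standard deviation. Each Y column is offset by the
    average of its per-group means and left unscaled.

    Returns ``(centered_blocks, centered_Y, PreprocessState)``.

    Raises
    ------
    ValueError
        If any group is empty, or any feature has zero variance (its scale
        would be undefined).
    """
    labels = np.asarray(labels)
    for c in classes:
        if not np.any(labels == c):
            raise ValueError(f"empty group: {c!r}")
    x_offsets, x_scales, out_blocks = [], [], []
    for b, Xb in enumerate(blocks):
        Xb = np.asarray(Xb, dtype=float)
        sd = Xb.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance feature(s) in block {b}: indices {bad[:10].tolist()}"
            )
        off = group_mean_offsets(Xb, labels, classes)
        x_offsets.append(off)
        x_scales.append(sd)
        out_blocks.append((Xb - off) / sd)
    Y = np.asarray(Y, dtype=float)
    y_off = group_mean_offsets(Y, labels, classes)
    state = PreprocessState(x_offsets=x_offsets, x_scales=x_scales, y_offsets=y_off)
    return out_blocks, Y - y_off, state


def apply_center_scale(blocks, state: PreprocessState):
    """Apply stored offsets/scales to new data."""
    if len(blocks) != len(state.x_offsets):
        raise ValueError(
            f"expected {len(state.x_offsets)} blocks, got {len(blocks)}"
        )
    out = []
    for b, Xb in enumerate(blocks):
        Xb = np.asarray(Xb, dtype=float)
        if Xb.shape[1] != state.x_offsets[b].shape[0]:
            raise ValueError(
                f"block {b} has {Xb.shape[1]} features, model expects "
                f"{state.x_offsets[b].shape[0]}"
            )
        out.append((Xb - state.x_offsets[b]) / state.x_scales[b])
    return out


def soft_threshold(w, lam: float) -> np.ndarray:
    """Soft-thresholding ``sign(x) * max(|x| - lam, 0)``."""
    if lam < 0:
        raise ValueError(f"lam must be non-negative, got {lam}")
    w = np.asarray(w, dtype=float)
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def lambda_from_quantile(w, quantile: float) -> float:
    """Threshold from the empirical quantile of the absolute weights.

    Uses the type-7 (linear interpolation) quantile of ``|w|``, so
    soft-thresholding leaves roughly ``(1 - quantile) * len(w)`` entries
    non-zero. A quantile of exactly 0 returns ``lam = 0`` (no shrinkage),
    the dense classical-PLS limit.
    """
    if not 0 <= quantile < 1:
        raise ValueError(f"quantile must be in [0, 1), got {quantile}")
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if quantile == 0:
        return 0.0
    return float(np.quantile(np.abs(w), quantile))


def _sparse_unit_weight(Xb: np.ndarray, u: np.ndarray, quantile: float, block: int) -> np.ndarray:
    w = Xb.T @ u
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError(f"block {block}: X^T u is identically zero")
    w = w / nrm
    lam = lambda_from_quantile(w, quantile)
    w = soft_threshold(w, lam)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError(
            f"block {block}: all weights zeroed by soft-thresholding at "
            f"quantile {quantile} (degenerate constant |w|)"
        )
    return w / nrm


def _fix_sign(v: np.ndarray) -> float:
    """Sign making the largest-magnitude entry positive (+1 or -1)."""
    i = int(np.argmax(np.abs(v)))
    return 1.0 if v[i] >= 0 else -1.0


def fit_component(blocks, Y, quantiles, max_iter: int = 500, tol: float = 1e-8) -> ComponentFit:
    """Extract one sparse multi-block PLS component from centred data.

    Iterates the NIPALS-style updates: per-block weight ``X_b^T u`` soft-
    thresholded and renormalised to unit norm on its support; block scores
    ``t_b = X_b w_b / sqrt(m_b)``; super weight from the stacked block
    scores; ``q`` from the Y side; ``u = Y q`` — until the super score
    stabilises. With a single-column Y this converges immediately.
    """
    quantiles = np.atleast_1d(np.asarray(quantiles, dtype=float))
    if quantiles.size == 1:
        quantiles = np.repeat(quantiles, len(blocks))
    if quantiles.size != len(blocks):
        raise ValueError(f"{quantiles.size} quantiles for {len(blocks)} blocks")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    sqrt_m = [np.sqrt(b.shape[1]) for b in blocks]

    u = Y[:, 0].copy()
    t_super_prev = None
    for it in range(1, max_iter + 1):
        ws = [
            _sparse_unit_weight(Xb, u, qb, b)
            for b, (Xb, qb) in enumerate(zip(blocks, quantiles))
        ]
        T = np.column_stack([Xb @ w / s for Xb, w, s in zip(blocks, ws, sqrt_m)])
        w_super = T.T @ u
        nrm = np.linalg.norm(w_super)
        if nrm == 0:
            raise ValueError("super weight collapsed to zero")
        w_super = w_super / nrm
        t_super = T @ w_super
        q = Y.T @ t_super
        qn = np.linalg.norm(q)
        if qn == 0:
            raise ValueError("outcome weight q collapsed to zero")
        q = q / qn
        u = Y @ q
        if t_super_prev is not None:
            denom = np.linalg.norm(t_super_prev)
            if denom == 0 or np.linalg.norm(t_super - t_super_prev) / denom < tol:
                break
        t_super_prev = t_super
    else:
        raise ValueError(
            f"component did not converge in {max_iter} iterations "
            f"(last relative change of t_super above {tol})"
        )

    # Fix the sign ambiguity: flip each weight vector so its largest-magnitude
    # entry is positive, propagating flips so all stored quantities stay
    # mutually consistent.
    signs = [_fix_sign(w) for w in ws]
    ws = [s * w for s, w in zip(signs, ws)]
    T = T * np.asarray(signs)
    w_super = T.T @ u
    w_super = w_super / np.linalg.norm(w_super)
    s_sup = _fix_sign(w_super)
    w_super = s_sup * w_super
    t_super = T @ w_super
    q = Y.T @ t_super
    q = q / np.linalg.norm(q)

    return ComponentFit(
        block_weights=ws,
        super_weight=w_super,
        q=q,
        quantiles_used=quantiles,
        t_super=t_super,
        n_iter=it,
    )


def block_scores(blocks, comp: ComponentFit) -> np.ndarray:
    """Block scores and super score of ``comp`` on (deflated) data."""
    T = np.column_stack(
        [
            Xb @ w / np.sqrt(Xb.shape[1])
            for Xb, w in zip(blocks, comp.block_weights)
        ]
    )
    return T @ comp.super_weight


def y_regression_loading(Y: np.ndarray, t_super: np.ndarray) -> np.ndarray:
    denom = float(t_super @ t_super)
    if denom == 0:
        raise ValueError("zero-norm super score")
    return Y.T @ t_super / denom


def deflate(blocks, Y, comp: ComponentFit):
    """Remove the rank-1 contribution of ``comp`` from X blocks and Y.

    Stores the regression loadings ``p_b = X_b^T t / (t^T t)`` and the Y
    loading on the component, then subtracts ``t p_b^T`` (resp. ``t g^T``).
    After deflation every block and Y are orthogonal to the super score.
    """
    t = comp.t_super
    denom = float(t @ t)
    if denom == 0:
        raise ValueError("zero-norm super score: cannot deflate")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    comp.block_loadings = [Xb.T @ t / denom for Xb in blocks]
    comp.y_loading = Y.T @ t / denom
    new_blocks = [Xb - np.outer(t, p) for Xb, p in zip(blocks, comp.block_loadings)]
    new_Y = Y - np.outer(t, comp.y_loading)
    return new_blocks, new_Y
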