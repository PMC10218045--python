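"""Scikit-learn style estimator for adaptive sparse multi-block PLS-DA.

``AsmbPLSDA`` fits a sequence of sparse multi-block PLS components to a set
of omics blocks and a categorical outcome, then classifies new samples with
one of the decision rules (or a vote over several). It follows the sklearn
estimator contract: constructor stores hyper-parameters unchanged, ``fit``
learns attributes with trailing underscores, and the object is clonable and
usable inside sklearn model selection.

X may be given as a list of per-block matrices, a
:class:`~asmbplsda.blocks.MultiBlockMatrix`, or a single 2-D matrix together
with the ``block_sizes`` hyper-parameter (column counts per block), which
makes the estimator usable in ordinary sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _core, rules
from .blocks import as_block_list, dummy_code


class AsmbPLSDA(BaseEstimator, ClassifierMixin):
    """Adaptive sparse multi-block PLS discriminant analysis.

    Parameters
    ----------
    n_components : int, default=1
        Number of PLS components J.
    quantiles : float, sequence, or 2-D array, default=0.0
        Sparsity quantiles in [0, 1): a scalar (shared), a length-B sequence
        (per block, shared across components), or a J x B table. Within each
        block roughly ``(1 - quantile) * m_b`` features keep non-zero weight.
    decision_rule : str, default="auto"
        One of ``fixed_cutoff | max_y | ed_super | ed_y | md_super | pca_md |
        vote_unweighted | vote_weighted | vote_ranked``; ``"auto"`` picks
        fixed cutoff (binary) or Max Y (multiclass).
    rule_performances : list of RulePerformance, optional
        Required by the weighted and ranked votes; typically produced by
        :func:`asmbplsda.model_selection.evaluate_rules_cv`.
    block_sizes : sequence of int, optional
        Column counts per block when X is passed as one concatenated matrix.
    max_iter, tol : NIPALS iteration controls.

    Attributes
    ----------
    classes_ : ndarray of group labels.
    components_ : list of :class:`~asmbplsda._core.ComponentFit`.
    preprocess_ : stored weighted-centring offsets and scales.
    super_scores_ : (n, J) training super scores.
    y_estimates_ : (n, c) training Y-estimates on the centred scale.
    quantile_table_ : (J, B) quantiles actually used.
    """

    def __init__(
        self,
        n_components: int = 1,
        quantiles=0.0,
        decision_rule: str = "auto",
        rule_performances=None,
        block_sizes=None,
        max_iter: int = 500,
        tol: float = 1e-8,
    ):
        self.n_components = n_components
        self.quantiles = quantiles
        self.decision_rule = decision_rule
        self.rule_performances = rule_performances
        self.block_sizes = block_sizes
        self.max_iter = max_iter
        self.tol = tol

    # -- helpers -----------------------------------------------------------

    def _blocks(self, X):
        return as_block_list(X, self.block_sizes)

    def _quantile_table(self, n_blocks: int) -> np.ndarray:
        q = np.asarray(self.quantiles, dtype=float)
        J = self.n_components
        if q.ndim == 0:
            table = np.full((J, n_blocks), float(q))
        elif q.ndim == 1:
            if q.size != n_blocks:
                raise ValueError(f"{q.size} quantiles for {n_blocks} blocks")
            table = np.tile(q, (J, 1))
        elif q.ndim == 2:
            if q.shape != (J, n_blocks):
                raise ValueError(
                    f"quantile table has shape {q.shape}, expected ({J}, {n_blocks})"
                )
            table = q.copy()
        else:
            raise ValueError("quantiles must be scalar, 1-D, or 2-D")
        if np.any((table < 0) | (table >= 1)):
            raise ValueError("quantiles must lie in [0, 1)")
        return table

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        blocks = self._blocks(X)
        outcome = dummy_code(y)
        self.classes_ = outcome.classes
        self.n_features_in_ = int(sum(b.shape[1] for b in blocks))
        table = self._quantile_table(len(blocks))

        Xd, Yd, state = _core.weighted_center_scale(
            blocks, outcome.Y, outcome.group_labels, outcome.classes
        )
        comps, scores = [], []
        for j in range(self.n_components):
            try:
                comp = _core.fit_component(
                    Xd, Yd, table[j], max_iter=self.max_iter, tol=self.tol
                )
                Xd, Yd = _core.deflate(Xd, Yd, comp)
            except ValueError as e:
                raise ValueError(f"component {j + 1}: {e}") from e
            comps.append(comp)
            scores.append(comp.t_super)

        self.components_ = comps
        self.preprocess_ = state
        self.quantile_table_ = table
        self.super_scores_ = np.column_stack(scores)
        self.y_estimates_ = self._accumulate_y(self.super_scores_)
        self._train_labels = np.asarray(y)
        self.geometry_ = rules.GroupGeometry.from_points(
            self.super_scores_, self._train_labels, self.classes_
        )
        return self

    def _accumulate_y(self, super_scores: np.ndarray) -> np.ndarray:
        c = self.components_[0].y_loading.shape[0]
        out = np.zeros((super_scores.shape[0], c))
        for j, comp in enumerate(self.components_):
            out += np.outer(super_scores[:, j], comp.y_loading)
        return out

    # -- prediction --------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Super scores of new samples, one column per component."""
        self._check_fitted()
        Xd = _core.apply_center_scale(self._blocks(X), self.preprocess_)
        cols = []
        for comp in self.components_:
            t = _core.block_scores(Xd, comp)
            cols.append(t)
            Xd = [Xb - np.outer(t, p) for Xb, p in zip(Xd, comp.block_loadings)]
        return np.column_stack(cols)

    def predict_y(self, X, n_components: int | None = None) -> np.ndarray:
        """Y-estimates on the centred scale (add ``preprocess_.y_offsets`` to
        return to the 0/1 dummy scale)."""
        self._check_fitted()
        J = len(self.components_)
        if n_components is None:
            n_components = J
        if not 0 <= n_components <= J:
            raise ValueError(f"n_components must be in [0, {J}]")
        T = self.transform(X)
        c = self.components_[0].y_loading.shape[0]
        out = np.zeros((T.shape[0], c))
        for j in range(n_components):
            out += np.outer(T[:, j], self.components_[j].y_loading)
        return out

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        T = self.transform(X)
        y_est = self._accumulate_y(T)
        rule = self.decision_rule
        if rule == "auto":
            rule = "fixed_cutoff" if len(self.classes_) == 2 else "max_y"
        return self._apply_rule(rule, y_est, T)

    def _apply_rule(self, rule: str, y_est: np.ndarray, T: np.ndarray) -> np.ndarray:
        offs = self.preprocess_.y_offsets
        if rule == "fixed_cutoff":
            return rules.classify_fixed_cutoff(y_est, offs, self.classes_)
        if rule == "max_y":
            return rules.classify_max_y(y_est, offs, self.classes_)
        if rule == "ed_super":
            return rules.classify_euclidean(T, self.geometry_)
        if rule == "md_super":
            return rules.classify_mahalanobis(T, self.geometry_)
        if rule == "ed_y":
            if len(self.classes_) < 3:
                raise ValueError("the ED-on-Y rule applies to multiclass outcomes only")
            geom = rules.GroupGeometry.from_points(
                self.y_estimates_, self._train_labels, self.classes_
            )
            return rules.classify_euclidean(y_est, geom)
        if rule == "pca_md":
            return rules.classify_pca_md(
                y_est, self.y_estimates_, self._train_labels, self.classes_
            )
        if rule in rules.VOTE_RULES:
            return self._apply_vote(rule, y_est, T)
        raise ValueError(f"unknown decision rule {rule!r}")

    def _apply_vote(self, rule: str, y_est: np.ndarray, T: np.ndarray) -> np.ndarray:
        single = rules.applicable_rules(len(self.classes_))
        labels = [self._apply_rule(r, y_est, T) for r in single]
        if rule == "vote_unweighted":
            return rules.vote_unweighted(labels)
        perfs = self.rule_performances
        if perfs is None:
            raise ValueError(
                f"{rule} requires rule_performances (per-rule CV metrics); "
                "see asmbplsda.model_selection.evaluate_rules_cv"
            )
        by_name = {p.rule: p for p in perfs}
        missing = [r for r in single if r not in by_name]
        if missing:
            raise ValueError(f"missing rule performance for: {missing}")
        ordered = [by_name[r] for r in single]
        if rule == "vote_weighted":
            return rules.vote_weighted(labels, ordered)
        return labels[rules.vote_ranked(ordered)]

    # -- introspection -----------------------------------------------------

    def selected_features(self) -> list[np.ndarray]:
        """Per block, the union over components of non-zero-weight indices."""
        self._check_fitted()
        B = len(self.components_[0].block_weights)
        out = []
        for b in range(B):
            idx = np.unique(
                np.concatenate([c.support[b] for c in self.components_])
            )
            out.append(idx)
        return out

    def _check_fitted(self):
        if not hasattr(self, "components_"):
            raise ValueError("this AsmbPLSDA instance is not fitted yet")


def fit_asmbplsda(X, y, quantile_table, n_components, **kwargs) -> AsmbPLSDA:
    """Functional wrapper around :class:`AsmbPLSDA` fitting."""
    return AsmbPLSDA(
        n_components=n_components, quantiles=quantile_table, **kwargs
    ).fit(X, y)
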