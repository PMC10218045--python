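"""Repeated stratified K-fold cross-validation for sparsity tuning.

Quantile combinations are tuned component by component: with the choices for
earlier components frozen, every candidate combination (cartesian product of
the per-block candidate lists) is scored for the current component by the CV
balanced accuracy

    BA_{NCV,K} = (1 / N_CV) * sum_nCV (1 / K) * sum_k BA_{nCV,k}

and the combination with the highest BA is fixed before moving on. The
number of components retained is then grown while adding a component raises
the BA by more than 0.005.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import _core, metrics, rules
from .blocks import as_block_list, dummy_code
from .estimator import AsmbPLSDA


@dataclass
class QuantileGrid:
    """Per-block candidate quantile lists, reused for every component."""

    per_block: list[list[float]]

    def __post_init__(self) -> None:
        if len(self.per_block) == 0:
            raise ValueError("grid needs at least one block")
        for b, cand in enumerate(self.per_block):
            if len(cand) == 0:
                raise ValueError(f"block {b}: empty candidate list")
            for q in cand:
                if not 0 <= q < 1:
                    raise ValueError(f"block {b}: quantile {q} outside [0, 1)")

    def combinations(self) -> list[tuple[float, ...]]:
        """Cartesian product of per-block candidates, in input order."""
        return list(itertools.product(*self.per_block))


@dataclass
class CVResult:
    """Outcome of the sequential quantile tuning."""

    quantile_table: np.ndarray       # J x B chosen combinations
    component_bas: np.ndarray        # BA_{NCV,K} of the chosen combination per component
    ba_tables: list[dict]            # per component: {combination: BA}
    n_components_selected: int
    rule: str


def stratified_repeated_folds(labels, K: int, n_cv: int, seed: int) -> np.ndarray:
    """N_CV independent stratified K-fold partitions.

    Returns an (n_cv, n) integer array of fold ids in 0..K-1. Within each
    partition, per-class fold counts differ by at most one. Deterministic
    given ``seed``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < K]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than K={K} samples; "
            "stratified folds are infeasible"
        )
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(n_cv) % (2**31)
    out = np.empty((n_cv, labels.size), dtype=int)
    for rep in range(n_cv):
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=int(states[rep]))
        for k, (_, val_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
            out[rep, val_idx] = k
    return out


def cv_balanced_accuracy(fold_bas) -> float:
    """Flat mean over the K x N_CV fold balanced accuracies."""
    arr = np.asarray(fold_bas, dtype=float)
    if arr.size == 0 or np.any(~np.isfinite(arr)):
        raise ValueError("missing or non-finite fold BA")
    return float(arr.mean())


class _FoldState:
    """Preprocessed, incrementally deflated data for one (repetition, fold)."""

    def __init__(self, blocks, y, train_idx, val_idx):
        y = np.asarray(y)
        self.y_train = y[train_idx]
        self.y_val = y[val_idx]
        outcome = dummy_code(self.y_train)
        self.classes = outcome.classes
        Xtr = [b[train_idx] for b in blocks]
        Xval = [b[val_idx] for b in blocks]
        self.Xd, self.Yd, self.state = _core.weighted_center_scale(
            Xtr, outcome.Y, self.y_train, self.classes
        )
        self.Xval = _core.apply_center_scale(Xval, self.state)
        c = self.Yd.shape[1]
        self.val_yhat = np.zeros((len(val_idx), c))
        self.train_yhat = np.zeros((len(train_idx), c))
        self.train_T: list[np.ndarray] = []
        self.val_T: list[np.ndarray] = []

    def try_component(self, quantiles, max_iter, tol):
        """Fit one candidate component without mutating the state.

        Returns (comp, y_loading, t_val) or raises ValueError.
        """
        comp = _core.fit_component(self.Xd, self.Yd, quantiles, max_iter=max_iter, tol=tol)
        y_load = _core.y_regression_loading(self.Yd, comp.t_super)
        t_val = _core.block_scores(self.Xval, comp)
        return comp, y_load, t_val

    def commit(self, comp, y_load, t_val):
        self.Xd, self.Yd = _core.deflate(self.Xd, self.Yd, comp)
        self.Xval = [
            Xb - np.outer(t_val, p) for Xb, p in zip(self.Xval, comp.block_loadings)
        ]
        self.val_yhat = self.val_yhat + np.outer(t_val, y_load)
        self.train_yhat = self.train_yhat + np.outer(comp.t_super, y_load)
        self.train_T.append(comp.t_super)
        self.val_T.append(t_val)

    def predict_candidate(self, rule, y_load, t_val, comp):
        """Validation-set labels using committed components plus a candidate."""
        y_est = self.val_yhat + np.outer(t_val, y_load)
        offs = self.state.y_offsets
        if rule == "fixed_cutoff":
            return rules.classify_fixed_cutoff(y_est, offs, self.classes)
        if rule == "max_y":
            return rules.classify_max_y(y_est, offs, self.classes)
        train_T = np.column_stack(self.train_T + [comp.t_super])
        val_T = np.column_stack(self.val_T + [t_val])
        if rule in ("ed_super", "md_super"):
            geom = rules.GroupGeometry.from_points(train_T, self.y_train, self.classes)
            fn = rules.classify_euclidean if rule == "ed_super" else rules.classify_mahalanobis
            return fn(val_T, geom)
        train_yhat = self.train_yhat + np.outer(comp.t_super, y_load)
        if rule == "ed_y":
            geom = rules.GroupGeometry.from_points(train_yhat, self.y_train, self.classes)
            return rules.classify_euclidean(y_est, geom)
        if rule == "pca_md":
            return rules.classify_pca_md(y_est, train_yhat, self.y_train, self.classes)
        raise ValueError(f"unsupported tuning rule {rule!r}")


def _default_rule(n_groups: int) -> str:
    return "fixed_cutoff" if n_groups == 2 else "max_y"


def tune_quantiles(
    X,
    y,
    grid: QuantileGrid | list,
    n_components: int = 3,
    K: int = 5,
    n_cv: int = 10,
    rule: str = "auto",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> CVResult:
    """Tune per-component quantile combinations by repeated stratified CV.

    Components are tuned sequentially: candidates for component l are scored
    with components < l frozen at their chosen combinations; the candidate
    with the highest BA_{NCV,K} wins (ties go to the first candidate in grid
    order). Candidates whose component fit fails score BA 0.
    """
    if not isinstance(grid, QuantileGrid):
        grid = QuantileGrid(list(grid))
    blocks = as_block_list(X)
    if len(grid.per_block) != len(blocks):
        raise ValueError(
            f"grid covers {len(grid.per_block)} blocks, data has {len(blocks)}"
        )
    y = np.asarray(y)
    classes = np.unique(y)
    if rule == "auto":
        rule = _default_rule(len(classes))
    folds = stratified_repeated_folds(y, K, n_cv, seed)

    states = []
    for rep in range(n_cv):
        for k in range(K):
            val_idx = np.flatnonzero(folds[rep] == k)
            train_idx = np.flatnonzero(folds[rep] != k)
            states.append(_FoldState(blocks, y, train_idx, val_idx))

    combos = grid.combinations()
    chosen_rows, chosen_bas, ba_tables = [], [], []
    for _ in range(n_components):
        ba_by_combo: dict[tuple[float, ...], float] = {}
        cache_best = None
        for combo in combos:
            if combo in ba_by_combo:
                continue
            fold_bas, fits = [], []
            failed = False
            for st in states:
                try:
                    comp, y_load, t_val = st.try_component(combo, max_iter, tol)
                    pred = st.predict_candidate(rule, y_load, t_val, comp)
                    fold_bas.append(metrics.balanced_accuracy(st.y_val, pred))
                    fits.append((comp, y_load, t_val))
                except ValueError:
                    failed = True
                    break
            ba = 0.0 if failed else cv_balanced_accuracy(fold_bas)
            ba_by_combo[combo] = ba
            if not failed and (cache_best is None or ba > cache_best[1]):
                cache_best = (combo, ba, fits)
        if cache_best is None:
            raise ValueError("every candidate combination failed to fit")
        combo, ba, fits = cache_best
        chosen_rows.append(combo)
        chosen_bas.append(ba)
        ba_tables.append(ba_by_combo)
        for st, (comp, y_load, t_val) in zip(states, fits):
            st.commit(comp, y_load, t_val)

    bas = np.asarray(chosen_bas)
    return CVResult(
        quantile_table=np.asarray(chosen_rows, dtype=float),
        component_bas=bas,
        ba_tables=ba_tables,
        n_components_selected=select_n_components(bas),
        rule=rule,
    )


def select_n_components(component_bas) -> int:
    """Grow the component count while BA_comp + 0.005 <= BA_{comp+1}."""
    bas = np.asarray(component_bas, dtype=float)
    if bas.size < 1:
        raise ValueError("need at least one component BA")
    comp = 1
    while comp < bas.size and bas[comp - 1] + 0.005 <= bas[comp]:
        comp += 1
    return comp


def evaluate_rules_cv(
    X,
    y,
    quantile_table,
    n_components: int,
    K: int = 5,
    n_cv: int = 10,
    seed: int = 0,
    rule_set=None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> list[rules.RulePerformance]:
    """Per-rule CV performance at a fixed (tuned) quantile combination.

    For each applicable decision rule, models are fitted on each training
    fold and scored on the validation fold; metrics are computed on the
    pooled out-of-fold predictions. The resulting records feed the weighted
    and ranked votes.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if rule_set is None:
        rule_set = rules.applicable_rules(len(classes))
    blocks = as_block_list(X)
    table = np.asarray(quantile_table, dtype=float)[:n_components]
    folds = stratified_repeated_folds(y, K, n_cv, seed)
    true_all: list[np.ndarray] = []
    pred_all: dict[str, list[np.ndarray]] = {r: [] for r in rule_set}
    for rep in range(n_cv):
        for k in range(K):
            val_idx = np.flatnonzero(folds[rep] == k)
            train_idx = np.flatnonzero(folds[rep] != k)
            model = AsmbPLSDA(
                n_components=n_components, quantiles=table, max_iter=max_iter, tol=tol
            ).fit([b[train_idx] for b in blocks], y[train_idx])
            Xval = [b[val_idx] for b in blocks]
            T = model.transform(Xval)
            y_est = model._accumulate_y(T)
            true_all.append(y[val_idx])
            for r in rule_set:
                pred_all[r].append(model._apply_rule(r, y_est, T))
    y_true = np.concatenate(true_all)
    out = []
    for r in rule_set:
        rep = metrics.classification_report(y_true, np.concatenate(pred_all[r]), labels=classes)
        out.append(
            rules.RulePerformance(
                rule=r,
                balanced_accuracy=rep.balanced_accuracy,
                accuracy=rep.accuracy,
                recall=rep.recall,
                precision=rep.precision,
                f1=rep.f1,
            )
        )
    return out
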