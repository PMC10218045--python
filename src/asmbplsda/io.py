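"""Matrix and model I/O, run configuration, and the two-stage export.

Matrices are delimited text (CSV/TSV) with a header row of feature names and
the sample ID in the first column. Blocks may come as one file per block or
as a single matrix plus a block map (feature -> block). Models serialise to
JSON; Python's shortest-repr float encoding makes the round trip bit-exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _core, metrics, model_selection, rules
from .blocks import MultiBlockMatrix
from .estimator import AsmbPLSDA

logger = logging.getLogger("asmbplsda")

_FORMAT_VERSION = 1


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def _check_numeric(df: pd.DataFrame, path) -> None:
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric column(s): {list(bad[:5])}")
    if df.isna().any().any():
        loc = np.argwhere(df.isna().values)[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[loc[0]]!r}, "
            f"column {df.columns[loc[1]]!r}"
        )


def read_outcome(path) -> pd.Series:
    """Two-column file: sample ID, group label."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: outcome file must have exactly two columns")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    return s


def read_blocks(block_paths=None, outcome_path=None, matrix_path=None, block_map_path=None):
    """Load per-block matrices plus the outcome, row-aligned by sample ID.

    Either ``block_paths`` (one delimited file per block) or ``matrix_path``
    plus ``block_map_path`` (two columns: feature, block) must be given.
    Returns ``(MultiBlockMatrix, labels ndarray)``.
    """
    if outcome_path is None:
        raise ValueError("an outcome file is required")
    outcome = read_outcome(outcome_path)
    if matrix_path is not None:
        if block_map_path is None:
            raise ValueError("a block map is required with a single matrix")
        full = _read_table(matrix_path)
        _check_numeric(full, matrix_path)
        bmap = pd.read_csv(block_map_path, sep=None, engine="python", index_col=0)
        missing = set(full.columns) - set(bmap.index.astype(str))
        if missing:
            raise ValueError(f"block map is missing feature(s): {sorted(missing)[:5]}")
        assign = bmap.iloc[:, 0].astype(str)
        block_names = list(dict.fromkeys(assign.loc[full.columns]))
        frames = [full.loc[:, [c for c in full.columns if assign[c] == bn]] for bn in block_names]
    else:
        if not block_paths:
            raise ValueError("give block files or a matrix plus a block map")
        frames = []
        for path in block_paths:
            df = _read_table(path)
            if df.index.duplicated().any():
                raise ValueError(f"{path}: duplicate sample IDs")
            if df.columns.duplicated().any():
                raise ValueError(f"{path}: duplicate feature names")
            _check_numeric(df, path)
            frames.append(df)
    ids = frames[0].index
    for i, df in enumerate(frames[1:], start=1):
        if set(df.index) != set(ids):
            raise ValueError(
                f"sample IDs of block {i} do not match block 0: "
                f"e.g. {sorted(set(ids) ^ set(df.index))[:5]}"
            )
    if set(outcome.index) != set(ids):
        raise ValueError("outcome sample IDs do not match the block files")
    frames = [df.loc[ids] for df in frames]  # realign rows by ID
    X = MultiBlockMatrix(
        blocks=[df.values.astype(float) for df in frames],
        feature_names=[list(df.columns) for df in frames],
        sample_ids=list(ids),
    )
    return X, outcome.loc[ids].values


def write_blocks(X: MultiBlockMatrix, y, outdir, prefix="") -> list[Path]:
    """Write one CSV per block plus the outcome file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = X.sample_ids or [f"S{i + 1}" for i in range(X.n_samples)]
    paths = []
    for b, block in enumerate(X.blocks):
        names = (
            X.feature_names[b]
            if X.feature_names
            else [f"b{b + 1}_f{j + 1}" for j in range(block.shape[1])]
        )
        path = outdir / f"{prefix}block{b + 1}.csv"
        pd.DataFrame(block, index=ids, columns=names).to_csv(path, index_label="sample")
        paths.append(path)
    ypath = outdir / f"{prefix}outcome.csv"
    pd.Series(y, index=ids, name="group").to_csv(ypath, index_label="sample")
    paths.append(ypath)
    return paths


# -- model serialisation ---------------------------------------------------


def _arr(a):
    return np.asarray(a).tolist()


def save_model(model: AsmbPLSDA, path) -> None:
    """Serialise a fitted model to JSON (bit-exact round trip)."""
    model._check_fitted()
    st = model.preprocess_
    doc = {
        "format_version": _FORMAT_VERSION,
        "params": {
            "n_components": model.n_components,
            "decision_rule": model.decision_rule,
            "block_sizes": list(model.block_sizes) if model.block_sizes else None,
            "max_iter": model.max_iter,
            "tol": model.tol,
        },
        "classes": _arr(model.classes_),
        "classes_dtype": str(model.classes_.dtype),
        "quantile_table": _arr(model.quantile_table_),
        "preprocess": {
            "x_offsets": [_arr(o) for o in st.x_offsets],
            "x_scales": [_arr(s) for s in st.x_scales],
            "y_offsets": _arr(st.y_offsets),
        },
        "components": [
            {
                "block_weights": [_arr(w) for w in c.block_weights],
                "super_weight": _arr(c.super_weight),
                "q": _arr(c.q),
                "quantiles_used": _arr(c.quantiles_used),
                "t_super": _arr(c.t_super),
                "block_loadings": [_arr(p) for p in c.block_loadings],
                "y_loading": _arr(c.y_loading),
                "n_iter": c.n_iter,
            }
            for c in model.components_
        ],
        "train_labels": _arr(model._train_labels),
        "rule_performances": None
        if model.rule_performances is None
        else [vars(p) for p in model.rule_performances],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> AsmbPLSDA:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')}")
    perfs = doc["rule_performances"]
    model = AsmbPLSDA(
        quantiles=np.asarray(doc["quantile_table"]),
        rule_performances=None if perfs is None else [rules.RulePerformance(**p) for p in perfs],
        **doc["params"],
    )
    model.classes_ = np.asarray(doc["classes"], dtype=doc["classes_dtype"])
    model.quantile_table_ = np.asarray(doc["quantile_table"])
    pp = doc["preprocess"]
    model.preprocess_ = _core.PreprocessState(
        x_offsets=[np.asarray(o) for o in pp["x_offsets"]],
        x_scales=[np.asarray(s) for s in pp["x_scales"]],
        y_offsets=np.asarray(pp["y_offsets"]),
    )
    model.components_ = [
        _core.ComponentFit(
            block_weights=[np.asarray(w) for w in c["block_weights"]],
            super_weight=np.asarray(c["super_weight"]),
            q=np.asarray(c["q"]),
            quantiles_used=np.asarray(c["quantiles_used"]),
            t_super=np.asarray(c["t_super"]),
            block_loadings=[np.asarray(p) for p in c["block_loadings"]],
            y_loading=np.asarray(c["y_loading"]),
            n_iter=c["n_iter"],
        )
        for c in doc["components"]
    ]
    model.super_scores_ = np.column_stack([c.t_super for c in model.components_])
    model.y_estimates_ = model._accumulate_y(model.super_scores_)
    model._train_labels = np.asarray(doc["train_labels"], dtype=doc["classes_dtype"])
    model.n_features_in_ = int(sum(o.size for o in model.preprocess_.x_offsets))
    model.geometry_ = rules.GroupGeometry.from_points(
        model.super_scores_, model._train_labels, model.classes_
    )
    return model


# -- two-stage export ------------------------------------------------------


def export_two_stage(model: AsmbPLSDA, X, mode: str = "super_scores"):
    """Predictors for a downstream classifier (LDA, RF, ...).

    ``super_scores`` exports the n x J super-score matrix; ``selected_features``
    exports the original-scale submatrix of features with non-zero weight in
    any component, with block provenance in the metadata.
    """
    model._check_fitted()
    if mode == "super_scores":
        M = model.transform(X)
        meta = {"mode": mode, "columns": [f"t_super_{j + 1}" for j in range(M.shape[1])]}
        return M, meta
    if mode == "selected_features":
        support = model.selected_features()
        if all(len(s) == 0 for s in support):
            raise ValueError("no features selected: nothing to export")
        blocks = model._blocks(X)
        M = np.concatenate([b[:, s] for b, s in zip(blocks, support)], axis=1)
        meta = {
            "mode": mode,
            "block": np.concatenate(
                [np.full(len(s), b) for b, s in enumerate(support)]
            ).tolist(),
            "feature_index": np.concatenate(support).tolist(),
        }
        return M, meta
    raise ValueError(f"unknown export mode {mode!r}")


def fit_two_stage(model: AsmbPLSDA, X, y, classifier="rf", mode="selected_features",
                  random_state=0):
    """Fit a downstream classifier on the exported predictors.

    Returns the fitted sklearn classifier; use :func:`predict_two_stage` for
    new data with the same asmbPLS-DA model.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier

    M, _ = export_two_stage(model, X, mode)
    if classifier == "lda":
        clf = LinearDiscriminantAnalysis()
    elif classifier == "rf":
        clf = RandomForestClassifier(random_state=random_state)
    else:
        raise ValueError(f"unknown downstream classifier {classifier!r}")
    return clf.fit(M, y)


def predict_two_stage(model: AsmbPLSDA, clf, X, mode="selected_features"):
    M, _ = export_two_stage(model, X, mode)
    return clf.predict(M)


# -- pipeline --------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one tune-fit-evaluate run."""

    block_paths: list[str]
    outcome_path: str
    outdir: str
    quantile_grid: list[list[float]]
    n_components: int = 3
    K: int = 5
    n_cv: int = 10
    rule: str = "auto"
    seed: int = 0
    test_block_paths: list[str] | None = None
    test_outcome_path: str | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in doc.items() if k in known}
        kwargs["extra"] = {k: v for k, v in doc.items() if k not in known}
        missing = [k for k in ("block_paths", "outcome_path", "outdir", "quantile_grid") if k not in kwargs]
        if missing:
            raise ValueError(f"config is missing required key(s): {missing}")
        return cls(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Tune, fit, predict and evaluate; write all artifacts to ``outdir``.

    Writes the CV table, the model JSON, per-sample predictions, a metrics
    report and a run log recording the seed. Returns a summary dict.
    """
    for path in [*config.block_paths, config.outcome_path]:
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        from . import __version__

        logger.info("asmbplsda %s, seed=%d", __version__, config.seed)
        X, y = read_blocks(config.block_paths, config.outcome_path)
        logger.info(
            "loaded %d samples, %d blocks (%s features)",
            X.n_samples, X.n_blocks, "+".join(map(str, X.block_sizes)),
        )
        cv = model_selection.tune_quantiles(
            X.blocks, y, config.quantile_grid,
            n_components=config.n_components, K=config.K, n_cv=config.n_cv,
            rule=config.rule, seed=config.seed,
        )
        rows = []
        for j, table in enumerate(cv.ba_tables):
            for combo, ba in table.items():
                rows.append({"component": j + 1,
                             **{f"quantile_block{b + 1}": q for b, q in enumerate(combo)},
                             "balanced_accuracy": ba})
        pd.DataFrame(rows).to_csv(outdir / "cv_table.csv", index=False)
        J = cv.n_components_selected
        logger.info("selected %d component(s); CV BA per component: %s",
                    J, np.round(cv.component_bas, 4).tolist())

        rule = config.rule
        classes = np.unique(y)
        perfs = None
        if rule in rules.VOTE_RULES:
            perfs = model_selection.evaluate_rules_cv(
                X.blocks, y, cv.quantile_table, J,
                K=config.K, n_cv=config.n_cv, seed=config.seed,
            )
        model = AsmbPLSDA(
            n_components=J, quantiles=cv.quantile_table[:J],
            decision_rule=rule, rule_performances=perfs,
        ).fit(X.blocks, y)
        save_model(model, outdir / "model.json")

        if config.test_block_paths:
            Xev, yev = read_blocks(config.test_block_paths, config.test_outcome_path)
            ids = Xev.sample_ids
            Xev = Xev.blocks
        else:
            Xev, yev, ids = X.blocks, y, X.sample_ids
        pred = model.predict(Xev)
        pd.DataFrame({"sample": ids, "true": yev, "predicted": pred}).to_csv(
            outdir / "predictions.csv", index=False
        )
        report = metrics.classification_report(yev, pred, labels=classes)
        support = model.selected_features()
        summary = {
            "seed": config.seed,
            "rule": rule,
            "n_components": J,
            "quantile_table": cv.quantile_table[:J].tolist(),
            "cv_balanced_accuracy": cv.component_bas[:J].tolist(),
            "n_selected_per_block": [int(len(s)) for s in support],
            "selected_features": [
                [X.feature_names[b][i] for i in s] if X.feature_names else s.tolist()
                for b, s in enumerate(support)
            ],
            "report": report.to_dict(),
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2))
        logger.info("evaluation accuracy %.4f, BA %.4f",
                    report.accuracy, report.balanced_accuracy)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
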