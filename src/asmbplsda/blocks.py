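"""Containers for multi-block predictor data and dummy-coded outcomes.

A multi-omics design matrix is a list of per-block sample x feature matrices
sharing one row order (one block per omics layer). The outcome is a vector of
group labels, dummy-coded internally: a single 0/1 column for two groups, one
indicator column per group for three or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultiBlockMatrix:
    """Ordered collection of per-block matrices with shared samples.

    Parameters
    ----------
    blocks : list of ndarray
        Each of shape (n_samples, m_b); all blocks share the row order.
    feature_names : list of list of str, optional
        Per-block feature identifiers, unique within a block.
    sample_ids : list of str, optional
        Length n_samples.
    """

    blocks: list[np.ndarray]
    feature_names: list[list[str]] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.blocks) == 0:
            raise ValueError("at least one block is required")
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        n = self.blocks[0].shape[0]
        for i, b in enumerate(self.blocks):
            if b.ndim != 2:
                raise ValueError(f"block {i} is not a 2-D matrix")
            if b.shape[0] != n:
                raise ValueError(
                    f"block {i} has {b.shape[0]} rows, expected {n}: "
                    "all blocks must share the sample order"
                )
            if b.shape[1] < 1:
                raise ValueError(f"block {i} has no features")
        if self.feature_names is not None:
            for i, (names, b) in enumerate(zip(self.feature_names, self.blocks)):
                if len(names) != b.shape[1]:
                    raise ValueError(f"block {i}: {len(names)} names for {b.shape[1]} features")
                if len(set(names)) != len(names):
                    raise ValueError(f"block {i}: duplicate feature names")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} samples")

    @property
    def n_samples(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_sizes(self) -> list[int]:
        return [b.shape[1] for b in self.blocks]


def as_block_list(X, block_sizes=None) -> list[np.ndarray]:
    """Coerce X to a list of per-block float arrays.

    Accepts a :class:`MultiBlockMatrix`, a list/tuple of matrices, or a single
    2-D matrix (optionally split by ``block_sizes``, column counts per block).
    """
    if isinstance(X, MultiBlockMatrix):
        return [np.asarray(b, dtype=float) for b in X.blocks]
    if isinstance(X, (list, tuple)):
        return list(MultiBlockMatrix([np.asarray(b) for b in X]).blocks)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D or a list of 2-D blocks")
    if block_sizes is None:
        return [X]
    if sum(block_sizes) != X.shape[1]:
        raise ValueError(
            f"block_sizes sum to {sum(block_sizes)} but X has {X.shape[1]} columns"
        )
    edges = np.cumsum([0] + list(block_sizes))
    return [X[:, edges[i]:edges[i + 1]] for i in range(len(block_sizes))]


@dataclass
class OutcomeMatrix:
    """Dummy-coded outcome: one column for two groups, G columns for G >= 3."""

    Y: np.ndarray
    group_labels: np.ndarray
    classes: np.ndarray
    group_sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.group_sizes = np.array(
            [np.sum(self.group_labels == c) for c in self.classes]
        )
        if np.any(self.group_sizes == 0):
            empty = self.classes[self.group_sizes == 0]
            raise ValueError(f"empty group(s): {list(empty)}")

    @property
    def n_groups(self) -> int:
        return len(self.classes)


def dummy_code(y) -> OutcomeMatrix:
    """Dummy-code group labels: n x 1 (binary) or n x G (multiclass)."""
    y = np.asarray(y)
    classes = np.unique(y)
    G = len(classes)
    if G < 2:
        raise ValueError("need at least two groups")
    if G == 2:
        Y = (y == classes[1]).astype(float)[:, None]
    else:
        Y = (y[:, None] == classes[None, :]).astype(float)
    return OutcomeMatrix(Y=Y, group_labels=y, classes=classes)
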