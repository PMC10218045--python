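"""Decision rules and vote schemes for translating PLS outputs into groups.

Five rules map Y-estimates or super scores onto group labels:

* ``fixed_cutoff`` (binary): re-shifted Y-estimate over 0.5 -> group 1.
* ``max_y`` (multiclass): argmax over the G estimate columns.
* Euclidean distance to group centroids (super scores, or Y-estimates for
  multiclass).
* Mahalanobis distance with the pooled within-group covariance
  ``S = [(n_1-1)S_1 + ... + (n_G-1)S_G] / (n - G)``.
* PCA + MD (multiclass): Mahalanobis distance on the first G-1 principal
  components of the training Y-estimates.

Three vote schemes combine several rules: unweighted plurality, a
BA-logit-weighted vote with ``weight_i = log(BA_i / (1 - BA_i))`` (0 for
BA <= 0.5), and a ranked vote picking the rule with the best combined rank
over five CV metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA

MAX_CONDITION = 1e12
_BA_CAP = 1.0 - 1e-6

Y_RULES = ("fixed_cutoff", "max_y", "ed_y", "pca_md")
SUPER_RULES = ("ed_super", "md_super")
VOTE_RULES = ("vote_unweighted", "vote_weighted", "vote_ranked")
ALL_RULES = Y_RULES + SUPER_RULES + VOTE_RULES


def applicable_rules(n_groups: int) -> list[str]:
    """Single rules applicable to an outcome with ``n_groups`` groups."""
    if n_groups == 2:
        return ["fixed_cutoff", "ed_super", "md_super"]
    return ["max_y", "ed_super", "ed_y", "md_super", "pca_md"]


@dataclass
class GroupGeometry:
    """Per-group centroids and pooled covariance in some feature space."""

    centroids: np.ndarray        # G x d
    pooled_cov: np.ndarray | None
    group_covs: list[np.ndarray | None]
    group_sizes: np.ndarray
    classes: np.ndarray

    @classmethod
    def from_points(cls, points, labels, classes=None) -> "GroupGeometry":
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[0] == 1 and np.asarray(labels).size != 1:
            points = points.T
        labels = np.asarray(labels)
        if classes is None:
            classes = np.unique(labels)
        cents, covs, sizes = [], [], []
        for c in classes:
            pts = points[labels == c]
            if pts.shape[0] == 0:
                raise ValueError(f"empty group: {c!r}")
            cents.append(pts.mean(axis=0))
            sizes.append(pts.shape[0])
            covs.append(np.cov(pts, rowvar=False, ddof=1) if pts.shape[0] > 1 else None)
        sizes = np.asarray(sizes)
        n, G, d = labels.size, len(classes), points.shape[1]
        if n > G:
            S = np.zeros((d, d))
            for ng, Sg in zip(sizes, covs):
                if ng > 1:
                    S += (ng - 1) * np.atleast_2d(Sg)
            S /= n - G
        else:
            S = None
        return cls(
            centroids=np.asarray(cents),
            pooled_cov=S,
            group_covs=covs,
            group_sizes=sizes,
            classes=np.asarray(classes),
        )


def _argmin_dist(d2: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # ties -> lowest group index
    return classes[np.argmin(d2, axis=1)]


def classify_fixed_cutoff(y_est, y_offsets, classes) -> np.ndarray:
    """Binary rule: re-shifted Y-estimate over 0.5 -> group 1, else group 0.

    A value of exactly 0.5 goes to group 0.
    """
    classes = np.asarray(classes)
    if len(classes) != 2:
        raise ValueError("fixed cutoff applies to binary outcomes only")
    y_est = np.asarray(y_est, dtype=float)
    shifted = y_est.reshape(-1) + np.asarray(y_offsets).reshape(-1)[0]
    return np.where(shifted > 0.5, classes[1], classes[0])


def classify_max_y(y_est, y_offsets, classes) -> np.ndarray:
    """Multiclass rule: assign to the group with the maximum Y-estimate."""
    classes = np.asarray(classes)
    if len(classes) < 3:
        raise ValueError("Max Y applies to multiclass outcomes only")
    y_est = np.asarray(y_est, dtype=float) + np.asarray(y_offsets)[None, :]
    return classes[np.argmax(y_est, axis=1)]


def classify_euclidean(points, geometry: GroupGeometry) -> np.ndarray:
    """Assign each point to the group with the nearest centroid."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != geometry.centroids.shape[1]:
        raise ValueError(
            f"points have dimension {points.shape[1]}, centroids "
            f"{geometry.centroids.shape[1]}"
        )
    diff = points[:, None, :] - geometry.centroids[None, :, :]
    d2 = np.einsum("igd,igd->ig", diff, diff)
    return _argmin_dist(d2, geometry.classes)


def classify_mahalanobis(points, geometry: GroupGeometry) -> np.ndarray:
    """Assign by smallest Mahalanobis distance under the pooled covariance."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    S = geometry.pooled_cov
    if S is None:
        raise ValueError(
            "pooled covariance unavailable (too few samples); use the "
            "Euclidean-distance rule instead"
        )
    S = np.atleast_2d(S)
    if points.shape[1] != S.shape[0]:
        raise ValueError("dimension mismatch between points and covariance")
    if np.linalg.cond(S) >= MAX_CONDITION:
        raise ValueError(
            "pooled covariance is singular or ill-conditioned; use the "
            "Euclidean-distance rule instead"
        )
    Sinv = np.linalg.inv(S)
    diff = points[:, None, :] - geometry.centroids[None, :, :]
    d2 = np.einsum("igd,de,ige->ig", diff, Sinv, diff)
    return _argmin_dist(d2, geometry.classes)


def classify_pca_md(y_est_new, y_est_train, train_labels, classes=None) -> np.ndarray:
    """Multiclass rule: MD on the first G-1 principal components of Y-estimates.

    The PCA is fitted on the training Y-estimates; both training and new
    estimates are projected before recomputing the group geometry.
    """
    y_est_train = np.asarray(y_est_train, dtype=float)
    train_labels = np.asarray(train_labels)
    if classes is None:
        classes = np.unique(train_labels)
    G = len(classes)
    if G < 3:
        raise ValueError("PCA + MD applies to multiclass outcomes only")
    centered = y_est_train - y_est_train.mean(axis=0)
    if np.linalg.matrix_rank(centered) < G - 1:
        raise ValueError(
            f"training Y-estimates have rank below G-1={G - 1}; "
            "the PC projection is undefined"
        )
    pca = PCA(n_components=G - 1)
    train_pc = pca.fit_transform(y_est_train)
    new_pc = pca.transform(np.atleast_2d(np.asarray(y_est_new, dtype=float)))
    geom = GroupGeometry.from_points(train_pc, train_labels, classes)
    return classify_mahalanobis(new_pc, geom)


@dataclass
class RulePerformance:
    """CV performance of one decision rule at the tuned quantile combination."""

    rule: str
    balanced_accuracy: float
    accuracy: float
    recall: float
    precision: float
    f1: float

    @property
    def weight(self) -> float:
        """BA-logit vote weight, 0 for BA <= 0.5, capped near BA = 1."""
        return vote_weight(self.balanced_accuracy)

    def metric_vector(self) -> np.ndarray:
        for name, v in (
            ("balanced_accuracy", self.balanced_accuracy),
            ("accuracy", self.accuracy),
            ("recall", self.recall),
            ("precision", self.precision),
            ("f1", self.f1),
        ):
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing metric {name!r} for rule {self.rule!r}")
        return np.array(
            [self.balanced_accuracy, self.accuracy, self.recall, self.precision, self.f1]
        )


def vote_weight(ba: float) -> float:
    """log(BA / (1 - BA)), clamped to 0 for BA <= 0.5 and capped near 1."""
    if ba <= 0.5:
        return 0.0
    ba = min(ba, _BA_CAP)
    return float(np.log(ba / (1.0 - ba)))


def _plurality(rule_labels: list[np.ndarray], weights=None) -> np.ndarray:
    lengths = {len(np.asarray(l)) for l in rule_labels}
    if len(lengths) != 1:
        raise ValueError("rule label vectors have inconsistent lengths")
    if len(rule_labels) < 2:
        raise ValueError("voting requires at least two rules")
    labels = [np.asarray(l) for l in rule_labels]
    n = len(labels[0])
    if weights is None:
        weights = np.ones(len(labels))
    out = np.empty(n, dtype=labels[0].dtype)
    for i in range(n):
        votes = [l[i] for l in labels]
        tally: dict = {}
        for v, w in zip(votes, weights):
            tally[v] = tally.get(v, 0.0) + w
        best = max(tally.values())
        # tie -> the earliest rule (in the order given) voting for a tied label
        for v in votes:
            if tally[v] == best:
                out[i] = v
                break
    return out


def vote_unweighted(rule_labels: list[np.ndarray]) -> np.ndarray:
    """Per-sample plurality over the rules; ties broken by rule order."""
    return _plurality(rule_labels)


def vote_weighted(rule_labels, performances: list[RulePerformance]) -> np.ndarray:
    """BA-logit weighted plurality; rules with BA <= 0.5 carry no weight."""
    if len(performances) != len(rule_labels):
        raise ValueError("need one performance record per rule")
    weights = np.array([p.weight for p in performances])
    return _plurality(list(rule_labels), weights)


def vote_ranked(performances: list[RulePerformance]) -> int:
    """Index of the rule with the highest combined rank over five metrics.

    Per metric, higher values get higher ranks; ties share average ranks.
    A tie on the combined rank goes to the earliest rule.
    """
    table = np.stack([p.metric_vector() for p in performances])
    ranks = np.stack([rankdata(table[:, j], method="average") for j in range(table.shape[1])], axis=1)
    combined = ranks.sum(axis=1)
    return int(np.argmax(combined))
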