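"""Synthetic multi-omics generator: two correlated MVN blocks with planted
relevant features and logistic/multinomial outcomes.

Each dataset has two predictor blocks. A "highly correlated" subset of
features (q_h in block 1, p_h in block 2) is drawn from one joint
multivariate normal with pairwise correlations Uniform(0.6, 0.9); the
remaining features form a second joint MVN with correlations
Uniform(-0.5, 0.5). Block-1 features have mean 0 and variance 1, block-2
features mean 5 and variance 3. Only the first ten features of block 1 and
the first five of block 2 carry non-zero outcome coefficients; the
``structure`` setting controls how many of those relevant positions land in
the highly correlated set (all / first 6+3 / random / none). The outcome is
drawn from a logistic (binary) or softmax-multinomial (three-group) model on
the centred-and-scaled blocks, with a noise term scaled by ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

N_RELEVANT = (10, 5)        # relevant features per block
N_RELEVANT_HC_ORDER = (6, 3)  # of which highly correlated under structure="order"
BETA_VAR = 5.0
NOISE_VAR = 5.0
STRUCTURES = ("cor", "order", "random", "inverse")


@dataclass
class SimulationScenario:
    """Full parameterisation of one simulation condition."""

    n: int = 100
    q: int = 1000
    q_h: int = 100
    p: int = 50
    p_h: int = 5
    structure: str = "cor"
    r: float = 0.0
    outcome: str = "binary"   # "binary" | "multiclass"
    seed: int = 0
    n_test: int | None = None

    def __post_init__(self) -> None:
        if self.q_h > self.q or self.p_h > self.p:
            raise ValueError("highly-correlated counts cannot exceed block sizes")
        if self.r < 0:
            raise ValueError("noise scale r must be non-negative")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.outcome not in ("binary", "multiclass"):
            raise ValueError(f"unknown outcome type {self.outcome!r}")

    @property
    def n_test_(self) -> int:
        return self.n if self.n_test is None else self.n_test


@dataclass
class SimulatedDataset:
    """One replicate: train/test blocks, labels and the planted truth."""

    X_train: list[np.ndarray]
    y_train: np.ndarray
    X_test: list[np.ndarray]
    y_test: np.ndarray
    relevant: list[np.ndarray]      # indices of relevant features per block
    beta: np.ndarray | list[np.ndarray]
    column_maps: list[np.ndarray]   # final position -> raw column (raw: HC first)
    is_highly_correlated: list[np.ndarray]
    scenario: SimulationScenario = field(repr=False, default=None)


def build_covariance(sds, c_low: float, c_high: float, rng) -> np.ndarray:
    """Covariance with correlations drawn Uniform(c_low, c_high), repaired
    to positive definiteness.

    Off-diagonals are ``c_ij * sd_i * sd_j`` with symmetric uniform draws.
    The raw matrix is generally indefinite, so eigenvalues are floored at
    ``1e-8 * max eigenvalue`` and the diagonal rescaled back to the target
    variances.
    """
    sds = np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    m = sds.size
    C = rng.uniform(c_low, c_high, size=(m, m))
    C = np.triu(C, 1)
    C = C + C.T
    np.fill_diagonal(C, 1.0)
    S = C * np.outer(sds, sds)
    if m == 1:
        return S
    vals, vecs = np.linalg.eigh(S)
    floor = 1e-8 * vals.max()
    if vals.min() < floor:
        vals = np.maximum(vals, floor)
        S = (vecs * vals) @ vecs.T
        S = (S + S.T) / 2
        d = sds / np.sqrt(np.diag(S))
        S = S * np.outer(d, d)
    return S


def apply_structure(structure: str, q: int, q_h: int, p: int, p_h: int, rng=None):
    """Column-order maps placing highly correlated features per structure.

    Raw columns are ordered highly-correlated first within each block; the
    returned per-block maps give, for each final position, the raw column it
    holds. Relevant features always occupy the first positions (10 in block
    1, 5 in block 2); the map controls whether those positions hold highly
    correlated columns: all (``cor``), exactly the first 6 and 3
    (``order``), a seeded random shuffle (``random``), or none
    (``inverse``).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    if structure == "random" and rng is None:
        raise ValueError("structure 'random' needs an rng")
    maps = []
    for (m, h, n_rel, n_rel_h) in (
        (q, q_h, N_RELEVANT[0], N_RELEVANT_HC_ORDER[0]),
        (p, p_h, N_RELEVANT[1], N_RELEVANT_HC_ORDER[1]),
    ):
        hc = np.arange(h)
        low = np.arange(h, m)
        if structure == "cor":
            if h < n_rel:
                raise ValueError(
                    f"structure 'cor' needs {n_rel} highly correlated features, have {h}"
                )
            order = np.concatenate([hc, low])
        elif structure == "order":
            if h < n_rel_h or m - h < n_rel - n_rel_h:
                raise ValueError("structure 'order' infeasible for these block sizes")
            order = np.concatenate(
                [hc[:n_rel_h], low[: n_rel - n_rel_h], hc[n_rel_h:], low[n_rel - n_rel_h:]]
            )
        elif structure == "inverse":
            if m - h < n_rel:
                raise ValueError(
                    f"structure 'inverse' needs {n_rel} non-highly-correlated features"
                )
            order = np.concatenate([low[:n_rel], hc, low[n_rel:]])
        else:  # random
            order = rng.permutation(m)
        maps.append(order)
    return maps


def simulate_blocks(scenario: SimulationScenario, rng, n_rows: int | None = None):
    """Draw the two raw blocks (highly-correlated columns first) and arrange
    them per the scenario's structure map.

    Returns ``(X1, X2, column_maps)``.
    """
    sc = scenario
    n = sc.n if n_rows is None else n_rows
    sd1, sd2 = 1.0, np.sqrt(3.0)
    mu1, mu2 = 0.0, 5.0
    # one joint draw couples block-1 and block-2 highly correlated features
    sds_h = np.concatenate([np.full(sc.q_h, sd1), np.full(sc.p_h, sd2)])
    mu_h = np.concatenate([np.full(sc.q_h, mu1), np.full(sc.p_h, mu2)])
    sds_l = np.concatenate([np.full(sc.q - sc.q_h, sd1), np.full(sc.p - sc.p_h, sd2)])
    mu_l = np.concatenate([np.full(sc.q - sc.q_h, mu1), np.full(sc.p - sc.p_h, mu2)])

    def draw(mu, sds, c_low, c_high):
        if sds.size == 0:
            return np.empty((n, 0))
        S = build_covariance(sds, c_low, c_high, rng)
        L = np.linalg.cholesky(S)
        return mu + rng.standard_normal((n, sds.size)) @ L.T

    H = draw(mu_h, sds_h, 0.6, 0.9)
    L_ = draw(mu_l, sds_l, -0.5, 0.5)
    raw1 = np.concatenate([H[:, : sc.q_h], L_[:, : sc.q - sc.q_h]], axis=1)
    raw2 = np.concatenate([H[:, sc.q_h :], L_[:, sc.q - sc.q_h :]], axis=1)
    maps = apply_structure(sc.structure, sc.q, sc.q_h, sc.p, sc.p_h, rng)
    return raw1[:, maps[0]], raw2[:, maps[1]], maps


def _scale(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def _draw_beta(rng) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(BETA_VAR), size=sum(N_RELEVANT))


def simulate_binary_outcome(X1, X2, r: float, rng, beta=None):
    """Bernoulli outcome from a logistic model on the scaled blocks.

    ``eta = X1s beta1 + X2s beta2 + r * e`` with ``e ~ N(0, 5 I)``; only the
    first 10 (block 1) and 5 (block 2) coefficients are non-zero, drawn
    ``N(0, 5)``.
    """
    X1s, X2s = _scale(np.asarray(X1)), _scale(np.asarray(X2))
    n = X1s.shape[0]
    if beta is None:
        beta = _draw_beta(rng)
    beta = np.asarray(beta, dtype=float)
    k1, k2 = N_RELEVANT
    eta = X1s[:, :k1] @ beta[:k1] + X2s[:, :k2] @ beta[k1 : k1 + k2]
    eta = eta + r * rng.normal(0.0, np.sqrt(NOISE_VAR), size=n)
    prob = expit(eta)
    y = rng.binomial(1, prob)
    return y, beta


def simulate_multiclass_outcome(X1, X2, r: float, rng, betas=None):
    """Three-group multinomial outcome with a zero-coefficient baseline class.

    Class 1 has the all-zero linear predictor; classes 2 and 3 each get an
    independent sparse coefficient vector (same design as the binary case)
    plus ``r * e_g`` noise. Class probabilities are the softmax of the three
    predictors (max-subtracted before exponentiation).
    """
    X1s, X2s = _scale(np.asarray(X1)), _scale(np.asarray(X2))
    n = X1s.shape[0]
    if betas is None:
        betas = [_draw_beta(rng), _draw_beta(rng)]
    k1, k2 = N_RELEVANT
    etas = [np.zeros(n)]
    for beta in betas:
        beta = np.asarray(beta, dtype=float)
        eta = X1s[:, :k1] @ beta[:k1] + X2s[:, :k2] @ beta[k1 : k1 + k2]
        etas.append(eta + r * rng.normal(0.0, np.sqrt(NOISE_VAR), size=n))
    E = np.column_stack(etas)
    E = E - E.max(axis=1, keepdims=True)
    prob = np.exp(E)
    prob /= prob.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(3, p=pi) for pi in prob])
    return y, betas


def generate_scenario(scenario: SimulationScenario) -> SimulatedDataset:
    """Generate one replicate: training set plus an independent test set.

    Train and test rows share one covariance draw, one structure map and one
    coefficient draw; they are sampled as a single MVN batch that is
    centred/scaled jointly before the outcome model is applied, then split.
    The returned X matrices are on the original (unscaled) scale.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_tot = sc.n + sc.n_test_
    X1, X2, maps = simulate_blocks(sc, rng, n_rows=n_tot)
    if sc.outcome == "binary":
        y, beta = simulate_binary_outcome(X1, X2, sc.r, rng)
    else:
        y, beta = simulate_multiclass_outcome(X1, X2, sc.r, rng)
    tr = slice(0, sc.n)
    te = slice(sc.n, n_tot)
    relevant = [np.arange(N_RELEVANT[0]), np.arange(N_RELEVANT[1])]
    is_hc = [maps[0] < sc.q_h, maps[1] < sc.p_h]
    return SimulatedDataset(
        X_train=[X1[tr], X2[tr]],
        y_train=y[tr],
        X_test=[X1[te], X2[te]],
        y_test=y[te],
        relevant=relevant,
        beta=beta,
        column_maps=maps,
        is_highly_correlated=is_hc,
        scenario=sc,
    )


def replicate_seeds(base_seed: int, n_replicates: int) -> np.ndarray:
    """Independent per-replicate seeds below 2**31, derived from one seed."""
    return np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)


def generate_replicates(scenario: SimulationScenario, n_replicates: int):
    """Independent replicates of one scenario (fresh covariance, map and
    coefficients per replicate)."""
    for s in replicate_seeds(scenario.seed, n_replicates):
        yield generate_scenario(replace(scenario, seed=int(s)))
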