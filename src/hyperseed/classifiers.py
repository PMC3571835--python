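"""Multiclass LS-SVM and momentum back-propagation network classifiers.

LS-SVM
------
The least-squares SVM replaces the quadratic program of the classical SVM
by one dense linear system. For a binary problem with labels y in {-1, +1}
and RBF kernel K(u, v) = exp(-||u - v||^2 / sigma2):

    [[0,  y^T          ],     [[b    ],     [[0],
     [y,  Omega + I/gamma]]  @  [alpha]]  =   [1]]

with Omega_ij = y_i y_j K(x_i, x_j); the decision value of a query x is
f(x) = sum_i alpha_i y_i K(x_i, x) + b. Note the RBF divisor here is
sigma2 itself (no factor 2), so the grid-searched sigma^2 matches the
usual LS-SVM toolbox convention; the KPCA module uses 2*sigma2.

Multiclass problems are handled one-vs-one with majority voting; vote ties
resolve to the earliest class in the ordered class list. Hyperparameters
(gamma, sigma2) are chosen by stratified k-fold grid search minimizing
RMSECV, the root mean squared error between integer class codes of the
held-out predictions and truths (class codes follow first appearance in
the training labels).

BPNN
----
A single-hidden-layer network (logistic sigmoid on hidden and output
layers) trained by batch gradient descent with classical momentum on the
mean squared error against one-hot targets. Prediction uses the +-0.5
band rule: a sample is assigned class c only when output unit c lies
within 0.5 of 1 AND every other unit lies within 0.5 of 0; otherwise it
is flagged unrecognized and counts as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, solve
from scipy.spatial.distance import cdist, squareform

from .errors import (
    DimensionError,
    DivergenceError,
    LabelError,
    NumericalError,
    ParameterError,
)

__all__ = [
    "LSSVMBinary",
    "LSSVMMulticlass",
    "BPNNModel",
    "GridSearchResult",
    "fit_lssvm_binary",
    "fit_lssvm",
    "predict_lssvm",
    "decision_value_lssvm",
    "grid_search_lssvm",
    "default_gamma_grid",
    "default_sigma2_grid",
    "fit_bpnn",
    "predict_bpnn",
    "vote_majority",
]


def default_gamma_grid() -> np.ndarray:
    """Regularization grid 2^-1 .. 2^10 (integer exponents)."""
    return 2.0 ** np.arange(-1, 11)


def default_sigma2_grid() -> np.ndarray:
    """RBF width grid 2^1 .. 2^15 (integer exponents)."""
    return 2.0 ** np.arange(1, 16)


def _rbf(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-cdist(A, B, metric="sqeuclidean") / sigma2)


# ---------------------------------------------------------------------------
# LS-SVM


@dataclass
class LSSVMBinary:
    support_X: np.ndarray
    y: np.ndarray  # +-1
    alpha: np.ndarray
    b: float
    gamma: float
    sigma2: float
    residual: float = 0.0  # relative residual of the linear solve


@dataclass
class LSSVMMulticlass:
    classes: list
    machines: dict  # (i, j) class-index pair -> LSSVMBinary, +1 = classes[i]
    gamma: float
    sigma2: float

    def to_dict(self) -> dict:
        return {
            "format": "hyperseed-lssvm-v1",
            "classes": [str(c) for c in self.classes],
            "gamma": self.gamma,
            "sigma2": self.sigma2,
            "machines": {
                f"{i},{j}": {
                    "support_X": m.support_X.tolist(),
                    "y": m.y.tolist(),
                    "alpha": m.alpha.tolist(),
                    "b": m.b,
                }
                for (i, j), m in self.machines.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMMulticlass":
        machines = {}
        for key, m in d["machines"].items():
            i, j = (int(t) for t in key.split(","))
            machines[(i, j)] = LSSVMBinary(
                np.array(m["support_X"]),
                np.array(m["y"]),
                np.array(m["alpha"]),
                float(m["b"]),
                d["gamma"],
                d["sigma2"],
            )
        return cls(list(d["classes"]), machines, d["gamma"], d["sigma2"])


def _solve_lssvm_system(K: np.ndarray, y: np.ndarray, gamma: float):
    """Assemble and solve the (n+1) x (n+1) LS-SVM system for (b, alpha)."""
    n = len(y)
    omega = np.outer(y, y) * K
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.zeros(n + 1)
    rhs[1:] = 1.0
    try:
        sol = solve(A, rhs, assume_a="sym")
    except LinAlgError as exc:
        raise NumericalError(
            "LS-SVM system is singular; try a smaller gamma (larger ridge jitter)"
        ) from exc
    residual = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if not np.all(np.isfinite(sol)):
        raise NumericalError("LS-SVM solve produced non-finite coefficients")
    return sol[0], sol[1:], residual


def fit_lssvm_binary(
    X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float
) -> LSSVMBinary:
    """Train one binary RBF LS-SVM by a direct dense solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if gamma <= 0 or sigma2 <= 0:
        raise ParameterError(f"gamma and sigma2 must be positive, got {gamma}, {sigma2}")
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise LabelError("binary LS-SVM needs both labels -1 and +1 present")
    K = _rbf(X, X, sigma2)
    b, alpha, residual = _solve_lssvm_system(K, y, gamma)
    return LSSVMBinary(X, y, alpha, float(b), gamma, sigma2, residual)


def decision_value_lssvm(model: LSSVMBinary, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i K(x_i, x) + b for each row of X."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.support_X.shape[1]:
        raise DimensionError("feature dimension mismatch")
    K = _rbf(X, model.support_X, model.sigma2)
    return K @ (model.alpha * model.y) + model.b


def fit_lssvm(
    X: np.ndarray, labels, gamma: float, sigma2: float, classes: list | None = None
) -> LSSVMMulticlass:
    """One-vs-one multiclass LS-SVM (C(C-1)/2 pairwise machines).

    Class order defaults to lexicographic; machine (i, j) codes classes[i]
    as +1 and classes[j] as -1.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise LabelError("need at least two classes")
    machines = {}
    for i, j in combinations(range(len(classes)), 2):
        mask = (labels == classes[i]) | (labels == classes[j])
        y = np.where(labels[mask] == classes[i], 1.0, -1.0)
        machines[(i, j)] = fit_lssvm_binary(X[mask], y, gamma, sigma2)
    return LSSVMMulticlass(list(classes), machines, gamma, sigma2)


def vote_majority(pair_signs: dict, n_classes: int, n_samples: int) -> np.ndarray:
    """Majority vote over pairwise decisions.

    ``pair_signs[(i, j)]`` holds per-sample signs (+1 votes class i,
    otherwise class j; a zero decision votes the earlier class i). Ties in
    the vote count go to the earliest class index.
    """
    votes = np.zeros((n_samples, n_classes), dtype=int)
    for (i, j), signs in pair_signs.items():
        win_i = signs >= 0
        votes[win_i, i] += 1
        votes[~win_i, j] += 1
    return np.argmax(votes, axis=1)  # argmax takes the earliest index on ties


def predict_lssvm(model: LSSVMMulticlass, X: np.ndarray):
    """Predict class labels by one-vs-one majority voting."""
    X = np.asarray(X, dtype=float)
    pair_signs = {
        pair: decision_value_lssvm(m, X) for pair, m in model.machines.items()
    }
    idx = vote_majority(pair_signs, len(model.classes), X.shape[0])
    return np.array([model.classes[i] for i in idx])


# ---------------------------------------------------------------------------
# Grid search


@dataclass
class GridSearchResult:
    best_gamma: float
    best_sigma2: float
    cv_surface: pd.DataFrame  # columns gamma, sigma2, rmsecv
    folds: int
    seed: int


def _stratified_folds(codes: np.ndarray, folds: int, rng: np.random.Generator):
    """Deal each class's shuffled indices round-robin into ``folds`` folds."""
    assignment = np.empty(len(codes), dtype=int)
    for c in np.unique(codes):
        idx = np.flatnonzero(codes == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def grid_search_lssvm(
    X: np.ndarray,
    labels,
    gamma_grid=None,
    sigma2_grid=None,
    folds: int = 10,
    seed: int = 0,
) -> GridSearchResult:
    """Stratified k-fold grid search minimizing RMSECV over (gamma, sigma2).

    RMSECV is the root mean squared difference between integer class codes
    (first-appearance order) of held-out predictions and truths. Ties are
    broken toward smaller sigma2, then smaller gamma.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    gamma_grid = np.sort(np.asarray(
        default_gamma_grid() if gamma_grid is None else gamma_grid, dtype=float))
    sigma2_grid = np.sort(np.asarray(
        default_sigma2_grid() if sigma2_grid is None else sigma2_grid, dtype=float))
    if gamma_grid.size == 0 or sigma2_grid.size == 0:
        raise ParameterError("hyperparameter grids must be non-empty")
    if folds < 2:
        raise ParameterError(f"folds must be >= 2, got {folds}")

    # Class codes by first appearance; class list for the pairwise machines
    # is ordered the same way so codes and vote indices agree.
    classes = list(dict.fromkeys(labels.tolist()))
    codes = np.array([classes.index(l) for l in labels])
    counts = np.bincount(codes)
    if counts.min() < folds:
        raise ParameterError(
            f"every class needs >= {folds} members for {folds}-fold stratified CV; "
            f"smallest class has {counts.min()}"
        )

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(codes, folds, rng)
    D2 = squareform(cdist(X, X, metric="sqeuclidean"), checks=False)
    D2 = squareform(D2)  # symmetrized dense matrix, zero diagonal
    n = len(labels)
    pairs = list(combinations(range(len(classes)), 2))

    rows = []
    best = None
    for sigma2 in sigma2_grid:
        K = np.exp(-D2 / sigma2)
        for gamma in gamma_grid:
            pred_codes = np.empty(n, dtype=int)
            for f in range(folds):
                test = np.flatnonzero(fold_of == f)
                train = np.flatnonzero(fold_of != f)
                pair_signs = {}
                for i, j in pairs:
                    tr = train[(codes[train] == i) | (codes[train] == j)]
                    y = np.where(codes[tr] == i, 1.0, -1.0)
                    b, alpha, _ = _solve_lssvm_system(K[np.ix_(tr, tr)], y, gamma)
                    pair_signs[(i, j)] = K[np.ix_(test, tr)] @ (alpha * y) + b
                pred_codes[test] = vote_majority(pair_signs, len(classes), len(test))
            rmsecv = float(np.sqrt(np.mean((pred_codes - codes) ** 2)))
            rows.append((gamma, sigma2, rmsecv))
            if best is None or rmsecv < best[2]:
                best = (gamma, sigma2, rmsecv)

    surface = pd.DataFrame(rows, columns=["gamma", "sigma2", "rmsecv"])
    return GridSearchResult(best[0], best[1], surface, folds, seed)


# ---------------------------------------------------------------------------
# BPNN


@dataclass
class BPNNModel:
    classes: list
    W1: np.ndarray  # d x H
    b1: np.ndarray
    W2: np.ndarray  # H x C
    b2: np.ndarray
    momentum: float
    learn_rate: float
    goal_mse: float
    max_epochs: int
    rng_seed: int
    loss_curve: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "format": "hyperseed-bpnn-v1",
            "classes": [str(c) for c in self.classes],
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "momentum": self.momentum,
            "learn_rate": self.learn_rate,
            "goal_mse": self.goal_mse,
            "max_epochs": self.max_epochs,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BPNNModel":
        return cls(
            list(d["classes"]),
            np.array(d["W1"]), np.array(d["b1"]),
            np.array(d["W2"]), np.array(d["b2"]),
            d["momentum"], d["learn_rate"], d["goal_mse"],
            d["max_epochs"], d["rng_seed"],
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_bpnn(
    X: np.ndarray,
    labels,
    hidden: int = 9,
    learn_rate: float = 0.5,
    momentum: float = 0.6,
    goal_mse: float = 1e-5,
    max_epochs: int = 1000,
    seed: int = 0,
    classes: list | None = None,
) -> BPNNModel:
    """Batch gradient descent with momentum on one-hot MSE.

    Defaults follow a classic small-network recipe: 9 hidden nodes,
    momentum 0.6, goal error 1e-5, 1000 epochs. Weights start
    uniform(-0.5, 0.5) from the seeded generator; training stops at the
    goal MSE or the epoch cap, whichever comes first.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if hidden < 1:
        raise ParameterError(f"hidden must be >= 1, got {hidden}")
    if not 0 <= momentum < 1:
        raise ParameterError(f"momentum must be in [0, 1), got {momentum}")
    if classes is None:
        classes = sorted(np.unique(labels).tolist())
    n, d = X.shape
    C = len(classes)
    T = np.zeros((n, C))
    for ci, c in enumerate(classes):
        T[labels == c, ci] = 1.0

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, size=(d, hidden))
    b1 = rng.uniform(-0.5, 0.5, size=hidden)
    W2 = rng.uniform(-0.5, 0.5, size=(hidden, C))
    b2 = rng.uniform(-0.5, 0.5, size=C)
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)

    curve = []
    for epoch in range(max_epochs):
        H = _sigmoid(X @ W1 + b1)
        O = _sigmoid(H @ W2 + b2)
        err = O - T
        mse = float(np.mean(err**2))
        curve.append(mse)
        if not np.isfinite(mse):
            raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch)
        if mse <= goal_mse:
            break
        dO = (2.0 / err.size) * err * O * (1.0 - O)
        dH = (dO @ W2.T) * H * (1.0 - H)
        gW2 = H.T @ dO; gb2 = dO.sum(axis=0)
        gW1 = X.T @ dH; gb1 = dH.sum(axis=0)
        vW2 = momentum * vW2 - learn_rate * gW2; W2 = W2 + vW2
        vb2 = momentum * vb2 - learn_rate * gb2; b2 = b2 + vb2
        vW1 = momentum * vW1 - learn_rate * gW1; W1 = W1 + vW1
        vb1 = momentum * vb1 - learn_rate * gb1; b1 = b1 + vb1

    return BPNNModel(
        list(classes), W1, b1, W2, b2, momentum, learn_rate, goal_mse,
        max_epochs, seed, np.array(curve),
    )


def bpnn_forward(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.W1.shape[0]:
        raise DimensionError("feature dimension mismatch")
    H = _sigmoid(X @ model.W1 + model.b1)
    return _sigmoid(H @ model.W2 + model.b2)


def apply_half_band_rule(outputs: np.ndarray, classes: list):
    """The +-0.5 recognition rule applied to raw network outputs.

    A row is recognized as class c iff output c is strictly within 0.5 of 1
    and every other output is strictly within 0.5 of 0.
    """
    near_one = np.abs(outputs - 1.0) < 0.5
    near_zero = np.abs(outputs) < 0.5
    ok = near_one & (near_zero.sum(axis=1, keepdims=True) == (outputs.shape[1] - 1)) \
        & ~near_zero
    valid = ok.sum(axis=1) == 1
    labels = np.empty(outputs.shape[0], dtype=object)
    labels[:] = None
    labels[valid] = [classes[i] for i in np.argmax(ok[valid], axis=1)]
    return labels, valid


def predict_bpnn(model: BPNNModel, X: np.ndarray):
    """Forward pass plus the +-0.5 band rule; returns (labels, valid flags)."""
    return apply_half_band_rule(bpnn_forward(model, X), model.classes)
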