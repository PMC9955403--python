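"""Neighborhood component analysis for regression, with a robust variant.

The weighted distance between observations is
``D(i,j) = sum_m w_m^2 |x_im - x_jm|`` and reference probabilities use the
kernel ``k(z) = exp(-z / sigma)`` normalized leave-one-out per row.  The
objective adds an L2 penalty ``lambda * sum w_m^2``.  The robust variant
(RNCA) uses the bounded loss ``zeta(a, b) = 1 - exp(-|a - b|)`` and tunes
lambda by k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..types import WeightVector

__all__ = ["NCAState", "mad_loss", "robust_loss", "nca_objective", "nca_fit",
           "rnca_tune"]

DEFAULT_LAMBDA = 0.015
DEFAULT_THRESHOLD = 3.0


def mad_loss(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs(a - b)


def robust_loss(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bounded loss zeta(a, b) = 1 - exp(-|a - b|)."""
    return 1.0 - np.exp(-np.abs(a - b))


_LOSSES = {"mad": mad_loss, "robust": robust_loss}


@dataclass
class NCAState:
    w: np.ndarray
    sigma: float = 1.0
    lam: float = DEFAULT_LAMBDA
    loss_kind: str = "mad"
    mean_: np.ndarray | None = None   # standardization applied to X at fit
    scale_: np.ndarray | None = None
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def _abs_diff_tensor(X: np.ndarray) -> np.ndarray:
    # A[i, j, m] = |x_im - x_jm|
    return np.abs(X[:, None, :] - X[None, :, :])


def nca_objective(state: NCAState, X: np.ndarray, y: np.ndarray,
                  _A: np.ndarray | None = None,
                  _L: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Objective F(w) and its analytic gradient.

    ``_A`` (pairwise absolute differences) and ``_L`` (pairwise losses) may
    be precomputed by the optimizer loop.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two observations")
    w = state.w
    sigma = state.sigma
    A = _abs_diff_tensor(X) if _A is None else _A
    if _L is None:
        loss = _LOSSES[state.loss_kind]
        L = loss(y[:, None], y[None, :])
    else:
        L = _L

    D = A @ (w ** 2)                       # n x n weighted distances
    if not np.all(np.isfinite(D)):
        raise FloatingPointError("pairwise distances overflowed")
    # Row-stabilized leave-one-out softmax: gamma is invariant to shifting
    # each row of D, which keeps exp() from underflowing for large w.
    Doff = D + np.diag(np.full(n, np.inf))
    K = np.exp(-(Doff - Doff.min(axis=1, keepdims=True)) / sigma)
    np.fill_diagonal(K, 0.0)
    Z = K.sum(axis=1)
    gamma = K / Z[:, None]

    Li = (gamma * L).sum(axis=1)
    F = float(Li.mean() + state.lam * (w ** 2).sum())

    M = gamma * L
    t1 = np.einsum("ij,ijm->m", M, A)          # sum_ij gamma l |dx|
    abar = np.einsum("ij,ijm->im", gamma, A)   # expected |dx| per row
    t2 = Li @ abar
    grad = -(2.0 * w / sigma) * (t1 - t2) / n + 2.0 * state.lam * w
    return F, grad


def nca_fit(X: np.ndarray, y: np.ndarray, lam: float = DEFAULT_LAMBDA,
            loss_kind: str = "mad", sigma: float = 1.0,
            standardize: bool = True, w0: np.ndarray | None = None,
            max_iter: int = 200, tol: float = 1e-6) -> NCAState:
    """Fit NCA weights by L-BFGS-B with nonnegativity bounds.

    X is standardized per feature by default (the state stores the
    transform); w is initialized to all-ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    n, p = X.shape
    mean_ = scale_ = None
    if standardize:
        mean_ = X.mean(axis=0)
        scale_ = X.std(axis=0)
        scale_ = np.where(scale_ > 0, scale_, 1.0)
        X = (X - mean_) / scale_

    A = _abs_diff_tensor(X)
    L = _LOSSES[loss_kind](y[:, None], y[None, :])
    state = NCAState(w=np.ones(p) if w0 is None else np.asarray(w0, float),
                     sigma=sigma, lam=lam, loss_kind=loss_kind)
    history: list[float] = []

    def fun(w):
        state.w = w
        F, g = nca_objective(state, X, y, _A=A, _L=L)
        return F, g

    def cb(w):
        state.w = w
        F, _ = nca_objective(state, X, y, _A=A, _L=L)
        history.append(F)

    res = minimize(fun, state.w.copy(), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * p, callback=cb,
                   options={"maxiter": max_iter, "ftol": tol})
    state.w = np.asarray(res.x, dtype=float)
    state.mean_, state.scale_ = mean_, scale_
    state.converged = bool(res.success)
    state.objective_history = history
    return state


def _apply_standardize(state: NCAState, X: np.ndarray) -> np.ndarray:
    if state.mean_ is None:
        return X
    return (X - state.mean_) / state.scale_


def nca_validation_loss(state: NCAState, X_train: np.ndarray, y_train: np.ndarray,
                        X_val: np.ndarray, y_val: np.ndarray) -> float:
    """Mean soft-neighbor loss of validation points against the train set."""
    Xt = _apply_standardize(state, np.asarray(X_train, float))
    Xv = _apply_standardize(state, np.asarray(X_val, float))
    D = np.abs(Xv[:, None, :] - Xt[None, :, :]) @ (state.w ** 2)
    K = np.exp(-D / state.sigma)
    Z = K.sum(axis=1)
    Z = np.where(Z > 0, Z, 1.0)
    gamma = K / Z[:, None]
    L = _LOSSES[state.loss_kind](np.asarray(y_val, float)[:, None],
                                 np.asarray(y_train, float)[None, :])
    return float((gamma * L).sum(axis=1).mean())


def default_lambda_grid(y: np.ndarray, num: int = 20) -> np.ndarray:
    """Linearly spaced lambda values in [0, 2*std(y)/n]."""
    y = np.asarray(y, dtype=float)
    return np.linspace(0.0, 2.0 * y.std() / len(y), num)


def _kfold(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for fold in np.array_split(perm, k):
        test = np.sort(fold)
        train = np.sort(np.setdiff1d(perm, fold))
        yield train, test


def rnca_tune(X: np.ndarray, y: np.ndarray,
              lambda_grid: np.ndarray | None = None, k: int = 5,
              threshold: float = DEFAULT_THRESHOLD, seed: int = 0,
              max_iter: int = 200) -> WeightVector:
    """Robust NCA: CV-tune lambda with the bounded loss, refit, rank weights.

    The fixed-threshold selection (w >= threshold, default 3) is reported
    in ``meta['selected']`` but the full ranking is always returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < k:
        raise ValueError("need at least k observations for k-fold CV")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")

    rng = np.random.default_rng(seed)
    folds = list(_kfold(n, k, rng))
    cv_loss = np.zeros(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        losses = []
        for train, test in folds:
            st = nca_fit(X[train], y[train], lam=lam, loss_kind="robust",
                         max_iter=max_iter)
            losses.append(nca_validation_loss(st, X[train], y[train],
                                              X[test], y[test]))
        cv_loss[i] = float(np.mean(losses))

    best = int(np.argmin(cv_loss))
    lam_b = float(lambda_grid[best])
    final = nca_fit(X, y, lam=lam_b, loss_kind="robust", max_iter=max_iter)
    weights = final.w
    ranking = np.argsort(-weights, kind="stable")
    selected = np.nonzero(weights >= threshold)[0]
    return WeightVector(method="RNCA", weights=weights, ranking=ranking,
                        meta={"lambda_b": lam_b,
                              "lambda_grid": lambda_grid.tolist(),
                              "cv_loss": cv_loss.tolist(),
                              "threshold": threshold,
                              "selected": selected.tolist(),
                              "converged": final.converged,
                              "seed": seed})
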