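"""Gaussian-process regression: squared-exponential kernel, explicit basis.

The kernel is ``amplitude * exp(-||x - x'||^2 / (2 eta^2))`` with a
separate observation-noise variance sigma2.  Basis weights have a closed
form given the kernel hyperparameters, so the log marginal likelihood is
profiled over them and the remaining three positive hyperparameters are
optimized in log space by multi-start L-BFGS with an analytic gradient.
Features are standardized internally; the transform is stored on the
model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = ["GPHyper", "GPModel", "se_kernel", "log_marginal_likelihood",
           "gp_fit", "gp_predict"]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


@dataclass
class GPHyper:
    eta: float
    sigma2: float
    kernel_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.sigma2 <= 0 or self.kernel_amplitude <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class GPModel:
    hyper: GPHyper
    X_train: np.ndarray          # standardized
    y_train: np.ndarray
    basis_kind: str              # 'constant' | 'linear'
    basis_w: np.ndarray
    phi: np.ndarray              # [K + sigma2 I]^-1 (y - Omega w)
    mean_: np.ndarray
    scale_: np.ndarray
    lml: float

    def to_dict(self) -> dict:
        d = {"eta": self.hyper.eta, "sigma2": self.hyper.sigma2,
             "kernel_amplitude": self.hyper.kernel_amplitude,
             "basis_kind": self.basis_kind,
             "basis_w": self.basis_w.tolist(),
             "X_train": self.X_train.tolist(),
             "y_train": self.y_train.tolist(),
             "phi": self.phi.tolist(),
             "mean": self.mean_.tolist(), "scale": self.scale_.tolist(),
             "lml": self.lml}
        blob = json.dumps({"X": d["X_train"], "y": d["y_train"]},
                          sort_keys=True).encode()
        d["training_checksum"] = hashlib.sha256(blob).hexdigest()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GPModel":
        return cls(hyper=GPHyper(d["eta"], d["sigma2"], d["kernel_amplitude"]),
                   X_train=np.asarray(d["X_train"], float),
                   y_train=np.asarray(d["y_train"], float),
                   basis_kind=d["basis_kind"],
                   basis_w=np.asarray(d["basis_w"], float),
                   phi=np.asarray(d["phi"], float),
                   mean_=np.asarray(d["mean"], float),
                   scale_=np.asarray(d["scale"], float),
                   lml=float(d["lml"]))


def se_kernel(x: np.ndarray, x2: np.ndarray, hyper: GPHyper) -> float:
    """Squared-exponential kernel between two points."""
    x = np.asarray(x, float).ravel()
    x2 = np.asarray(x2, float).ravel()
    if x.shape != x2.shape:
        raise ValueError("dimension mismatch")
    d2 = float(((x - x2) ** 2).sum())
    return hyper.kernel_amplitude * np.exp(-d2 / (2.0 * hyper.eta ** 2))


def _kernel_matrix(Xa: np.ndarray, Xb: np.ndarray, hyper: GPHyper) -> np.ndarray:
    d2 = cdist(Xa, Xb, metric="sqeuclidean")
    return hyper.kernel_amplitude * np.exp(-d2 / (2.0 * hyper.eta ** 2))


def _basis(X: np.ndarray, kind: str) -> np.ndarray:
    n = X.shape[0]
    if kind == "constant":
        return np.ones((n, 1))
    if kind == "linear":
        return np.hstack([np.ones((n, 1)), X])
    raise ValueError(f"unknown basis kind {kind!r}")


def _chol_with_jitter(C: np.ndarray):
    scale = float(np.mean(np.diag(C)))
    for jit in _JITTERS:
        try:
            return cho_factor(C + jit * scale * np.eye(len(C)), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("kernel system not positive definite")


def _lml_pieces(hyper: GPHyper, Xs: np.ndarray, y: np.ndarray, basis_kind: str,
                d2: np.ndarray | None = None):
    n = len(y)
    if d2 is None:
        d2 = cdist(Xs, Xs, metric="sqeuclidean")
    K = hyper.kernel_amplitude * np.exp(-d2 / (2.0 * hyper.eta ** 2))
    C = K + hyper.sigma2 * np.eye(n)
    cf = _chol_with_jitter(C)
    Omega = _basis(Xs, basis_kind)
    Ci_Omega = cho_solve(cf, Omega)
    Ci_y = cho_solve(cf, y)
    A = Omega.T @ Ci_Omega
    w = solve(A, Omega.T @ Ci_y, assume_a="pos")
    r = y - Omega @ w
    alpha = cho_solve(cf, r)
    logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
    lml = -0.5 * logdet - 0.5 * n * np.log(2 * np.pi) - 0.5 * float(r @ alpha)
    return lml, w, alpha, cf, K, d2, r


def log_marginal_likelihood(hyper: GPHyper, X: np.ndarray, y: np.ndarray,
                            basis_kind: str = "constant") -> float:
    """Profiled log marginal likelihood (basis weights at their maximizer)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    lml, *_ = _lml_pieces(hyper, X, y, basis_kind)
    return float(lml)


def _lml_and_grad(theta: np.ndarray, Xs: np.ndarray, y: np.ndarray,
                  basis_kind: str, d2: np.ndarray):
    """Negative profiled LML and gradient w.r.t. log hyperparameters.

    With the basis weights at their closed-form maximizer the envelope
    theorem lets us differentiate holding them fixed.
    """
    eta, sigma2, amp = np.exp(theta)
    hyper = GPHyper(eta=eta, sigma2=sigma2, kernel_amplitude=amp)
    n = len(y)
    lml, w, alpha, cf, K, _, r = _lml_pieces(hyper, Xs, y, basis_kind, d2)
    Ci = cho_solve(cf, np.eye(n))
    B = np.outer(alpha, alpha) - Ci

    dC_amp = K
    dC_eta = K * (d2 / eta ** 2)
    g_amp = 0.5 * float(np.sum(B * dC_amp))
    g_eta = 0.5 * float(np.sum(B * dC_eta))
    g_sig = 0.5 * sigma2 * float(np.trace(B))
    return -lml, -np.array([g_eta, g_sig, g_amp])


def gp_fit(X: np.ndarray, y: np.ndarray, basis_kind: str = "constant",
           n_restarts: int = 3, seed: int = 0, max_iter: int = 200,
           hyper0: GPHyper | None = None, optimize: bool = True) -> GPModel:
    """Fit hyperparameters by multi-start gradient ascent on the LML."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two observations")

    mean_ = X.mean(axis=0)
    scale_ = X.std(axis=0)
    scale_ = np.where(scale_ > 0, scale_, 1.0)
    Xs = (X - mean_) / scale_
    d2 = cdist(Xs, Xs, metric="sqeuclidean")

    var_y = float(np.var(y))
    if var_y <= 0:
        var_y = 1.0
    if hyper0 is None:
        med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
        hyper0 = GPHyper(eta=np.sqrt(med) if med > 0 else 1.0,
                         sigma2=max(0.1 * var_y, 1e-8),
                         kernel_amplitude=var_y)

    theta0 = np.log([hyper0.eta, hyper0.sigma2, hyper0.kernel_amplitude])
    if not optimize:
        best_theta = theta0
    else:
        rng = np.random.default_rng(seed)
        starts = [theta0] + [theta0 + rng.normal(0.0, 0.7, 3)
                             for _ in range(max(n_restarts - 1, 0))]
        best_val, best_theta = np.inf, theta0
        lo = np.log([1e-4, 1e-10 * max(var_y, 1.0), 1e-8 * max(var_y, 1.0)])
        hi = np.log([1e4, 1e4 * max(var_y, 1.0), 1e6 * max(var_y, 1.0)])
        bounds = list(zip(lo, hi))
        for t0 in starts:
            try:
                res = minimize(_lml_and_grad, np.clip(t0, lo, hi), jac=True,
                               args=(Xs, y, basis_kind, d2), method="L-BFGS-B",
                               bounds=bounds, options={"maxiter": max_iter})
            except np.linalg.LinAlgError:
                continue
            if res.fun < best_val:
                best_val, best_theta = float(res.fun), np.asarray(res.x)
        if not np.isfinite(best_val):
            raise RuntimeError("all optimizer starts failed")

    eta, sigma2, amp = np.exp(best_theta)
    hyper = GPHyper(eta=float(eta), sigma2=float(sigma2),
                    kernel_amplitude=float(amp))
    lml, w, alpha, *_ = _lml_pieces(hyper, Xs, y, basis_kind, d2)
    return GPModel(hyper=hyper, X_train=Xs, y_train=y, basis_kind=basis_kind,
                   basis_w=np.asarray(w, float), phi=np.asarray(alpha, float),
                   mean_=mean_, scale_=scale_, lml=float(lml))


def gp_predict(model: GPModel, X_new: np.ndarray,
               return_std: bool = False):
    """Posterior-mean prediction (basis term + kernel-weighted sum)."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError("dimension mismatch with training data")
    Xs = (X_new - model.mean_) / model.scale_
    Ks = _kernel_matrix(Xs, model.X_train, model.hyper)
    mean = _basis(Xs, model.basis_kind) @ model.basis_w + Ks @ model.phi
    if not return_std:
        return mean
    n = len(model.y_train)
    C = _kernel_matrix(model.X_train, model.X_train, model.hyper) \
        + model.hyper.sigma2 * np.eye(n)
    cf = _chol_with_jitter(C)
    v = cho_solve(cf, Ks.T)
    var = model.hyper.kernel_amplitude - np.einsum("ij,ji->i", Ks, v)
    return mean, np.sqrt(np.clip(var, 0.0, None))
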