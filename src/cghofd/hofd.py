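"""Hybrid optimal feature decision: GP-scored shrinking of a ranked set.

One of three filters (RNCA, F-test, MRMR) produces a descending feature
ranking; for every prefix size from ``start_size`` down to ``min_size``
the mean 5-fold cross-validated GP RMSE is recorded, on the same fold
partition, and the prefix with the minimal RMSE wins (ties break toward
fewer features).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalReport, eval_report
from .gpr import GPModel, gp_fit, gp_predict
from .types import FeatureTable, WeightVector
from .weighting import ftest_weights, mrmr_rank, rnca_tune

__all__ = ["HOFDConfig", "HOFDResult", "hofd_cv_rmse", "hofd_select",
           "run_pipeline", "derive_seed"]

_MODE_NAMES = {0: "rnca", 1: "ftest", 2: "mrmr"}


def derive_seed(seed: int, name: str) -> int:
    """Stage-local seed derived from the global seed and a stage name."""
    h = hashlib.blake2s(f"{seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "little")


@dataclass
class HOFDConfig:
    hybrid_mode: int | str = 0        # 0/'rnca', 1/'ftest', 2/'mrmr'
    start_size: int | None = 25
    min_size: int = 2
    cv_folds: int = 5
    seed: int = 0
    target: str = "SBP"
    gp_restarts: int = 1
    gp_max_iter: int = 100
    rnca_grid_size: int = 20
    rnca_cv_folds: int = 5

    def mode_name(self) -> str:
        if isinstance(self.hybrid_mode, str):
            name = self.hybrid_mode.lower()
            if name not in _MODE_NAMES.values():
                raise ValueError(f"unknown hybrid mode {self.hybrid_mode!r}")
            return name
        if self.hybrid_mode not in _MODE_NAMES:
            raise ValueError(f"unknown hybrid mode {self.hybrid_mode!r}")
        return _MODE_NAMES[self.hybrid_mode]


@dataclass
class HOFDResult:
    rmse_curve: list[tuple[int, float]]     # (subset_size, mean CV RMSE)
    best_size: int
    selected_indices: np.ndarray
    weights_used: WeightVector
    seed: int

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        curve = dict((s, v) for s, v in self.rmse_curve)
        assert curve[self.best_size] == min(v for _, v in self.rmse_curve)

    @property
    def best_rmse(self) -> float:
        return dict(self.rmse_curve)[self.best_size]

    def to_dict(self) -> dict:
        return {"rmse_curve": [[int(s), float(v)] for s, v in self.rmse_curve],
                "best_size": int(self.best_size),
                "selected_indices": self.selected_indices.tolist(),
                "weights": self.weights_used.to_dict(),
                "seed": int(self.seed)}


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


def hofd_cv_rmse(X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0,
                 partition=None, gp_restarts: int = 1,
                 gp_max_iter: int = 100) -> float:
    """Mean k-fold cross-validated GP RMSE on a feature subset."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError("require 2 <= folds <= n")
    if partition is None:
        partition = _kfold_indices(n, folds, np.random.default_rng(seed))
    rmses = []
    for train, test in partition:
        model = gp_fit(X[train], y[train], n_restarts=gp_restarts,
                       seed=seed, max_iter=gp_max_iter)
        pred = gp_predict(model, X[test])
        rmses.append(float(np.sqrt(np.mean((pred - y[test]) ** 2))))
    return float(np.mean(rmses))


def compute_weights(X: np.ndarray, y: np.ndarray, cfg: HOFDConfig) -> WeightVector:
    mode = cfg.mode_name()
    if mode == "ftest":
        return ftest_weights(X, y)
    if mode == "mrmr":
        return mrmr_rank(X, y, seed=derive_seed(cfg.seed, "mrmr"))
    from .weighting.nca import default_lambda_grid
    grid = default_lambda_grid(y, num=cfg.rnca_grid_size)
    return rnca_tune(X, y, lambda_grid=grid, k=cfg.rnca_cv_folds,
                     seed=derive_seed(cfg.seed, "rnca"))


def hofd_select(X: np.ndarray, y: np.ndarray, cfg: HOFDConfig,
                weights: WeightVector | None = None) -> HOFDResult:
    """Record the prefix CV-RMSE curve and decide the best feature subset."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two features")
    if weights is None:
        weights = compute_weights(X, y, cfg)
    ranking = weights.ranking
    start = min(cfg.start_size or p, p)
    if not (1 <= cfg.min_size <= start):
        raise ValueError("require 1 <= min_size <= start_size <= p")

    # One seeded partition shared across all candidate sizes, so curve
    # differences reflect subsets rather than fold luck.
    rng = np.random.default_rng(derive_seed(cfg.seed, "hofd-cv"))
    partition = _kfold_indices(n, cfg.cv_folds, rng)

    curve: list[tuple[int, float]] = []
    best_size, best_rmse = start, np.inf
    for num in range(start, cfg.min_size - 1, -1):
        idx = ranking[:num]
        nu = hofd_cv_rmse(X[:, idx], y, folds=cfg.cv_folds, seed=cfg.seed,
                          partition=partition, gp_restarts=cfg.gp_restarts,
                          gp_max_iter=cfg.gp_max_iter)
        curve.append((num, nu))
        # Ties break toward fewer features; sizes are visited descending.
        if nu <= best_rmse:
            best_rmse, best_size = nu, num
    return HOFDResult(rmse_curve=curve, best_size=best_size,
                      selected_indices=ranking[:best_size],
                      weights_used=weights, seed=cfg.seed)


@dataclass
class PipelineResult:
    hofd: HOFDResult
    model: GPModel
    report: EvalReport
    per_repeat: list[EvalReport] = field(default_factory=list)
    selected_names: list[str] = field(default_factory=list)


def _train_test_split(n: int, test_frac: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_test = max(int(round(test_frac * n)), 1)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def run_pipeline(table: FeatureTable, cfg: HOFDConfig, repeats: int = 1,
                 test_frac: float = 0.2) -> PipelineResult:
    """80/20 split, HOFD on the training split, final GP refit, evaluation.

    With ``repeats > 1`` the whole procedure is re-run on fresh splits with
    derived seeds and the reported metrics are averaged.
    """
    table = table.dropna()
    X = table.X
    y = table.y(cfg.target)
    n = len(y)
    reports: list[EvalReport] = []
    last = None
    for r in range(repeats):
        seed_r = derive_seed(cfg.seed, f"repeat-{r}") if repeats > 1 else cfg.seed
        rng = np.random.default_rng(derive_seed(seed_r, "split"))
        train, test = _train_test_split(n, test_frac, rng)
        if len(train) < cfg.cv_folds:
            raise ValueError("training split smaller than the CV fold count")
        cfg_r = HOFDConfig(**{**cfg.__dict__, "seed": seed_r})
        result = hofd_select(X[train], y[train], cfg_r)
        idx = result.selected_indices
        model = gp_fit(X[train][:, idx], y[train], n_restarts=cfg.gp_restarts,
                       seed=seed_r, max_iter=cfg.gp_max_iter)
        pred = gp_predict(model, X[test][:, idx])
        rep = eval_report(pred, y[test])
        reports.append(rep)
        last = (result, model)
    result, model = last
    mean_report = EvalReport.average(reports)
    names = [table.feature_names[i] for i in result.selected_indices]
    return PipelineResult(hofd=result, model=model, report=mean_report,
                          per_repeat=reports, selected_names=names)
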