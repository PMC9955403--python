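"""One-way-ANOVA F-test feature weighting for a continuous response.

Groups are instances with the same response value; a continuous response
is first discretized (default: rounded to the nearest integer mmHg) and
bins with fewer than two members are merged with their nearest neighbor.
Per feature, the F-score is the between/within mean-square ratio and the
weight is -log10(p) under the F(m-1, n-m) reference distribution.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..types import WeightVector

__all__ = ["group_response", "ftest_weights"]

_P_FLOOR = 1e-300  # keeps -log10(p) finite


def group_response(y: np.ndarray, binning: str | int = "integer") -> np.ndarray:
    """Group labels for the response.

    ``binning`` is either ``"integer"`` (round to nearest integer) or an
    integer number of equal-frequency quantile bins.  Groups with fewer
    than two members are merged with the nearest group by value.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(binning, str):
        if binning != "integer":
            raise ValueError(f"unknown binning rule {binning!r}")
        labels = np.round(y).astype(int)
    else:
        q = np.quantile(y, np.linspace(0, 1, int(binning) + 1)[1:-1])
        labels = np.searchsorted(np.unique(q), y)
    # Merge undersized groups with the nearest (by value) group.
    while True:
        vals, counts = np.unique(labels, return_counts=True)
        if len(vals) <= 1 or counts.min() >= 2:
            break
        small = vals[np.argmin(counts)]
        others = vals[vals != small]
        target = others[np.argmin(np.abs(others - small))]
        labels = np.where(labels == small, target, labels)
    return labels


def ftest_weights(X: np.ndarray, y: np.ndarray,
                  binning: str | int = "integer") -> WeightVector:
    """Per-feature F-scores over response-defined groups; weight = -log10(p)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    labels = group_response(y, binning)
    groups = np.unique(labels)
    m = len(groups)
    if m < 2:
        raise ValueError("need at least two response groups")

    fs = np.zeros(p)
    pvals = np.ones(p)
    for j in range(p):
        x = X[:, j]
        xbar = x.mean()
        sw = 0.0
        sb = 0.0
        for g in groups:
            xg = x[labels == g]
            mu = xg.mean()
            sw += float(((xg - mu) ** 2).sum())
            sb += len(xg) * float((mu - xbar) ** 2)
        if sw <= 0:
            if sb <= 0:
                fs[j], pvals[j] = 0.0, 1.0
                continue
            fs[j], pvals[j] = np.inf, _P_FLOOR
            continue
        f = (sb / (m - 1)) / (sw / (n - m))
        fs[j] = f
        pvals[j] = max(float(stats.f.sf(f, m - 1, n - m)), _P_FLOOR)

    weights = -np.log10(pvals)
    ranking = np.argsort(-weights, kind="stable")
    return WeightVector(method="FTEST", weights=weights, ranking=ranking,
                        meta={"F": fs.tolist(), "p": pvals.tolist(),
                              "significant": (pvals < 0.05).tolist(),
                              "n_groups": int(m)})
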