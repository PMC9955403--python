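"""Plug-in mutual information over binned contingency tables (nats)."""

from __future__ import annotations

import numpy as np

__all__ = ["discretize", "mutual_information"]

DEFAULT_BINS = 10


def discretize(a: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Integer codes for a column.

    Columns with at most ``bins`` distinct values are treated as discrete;
    otherwise equal-frequency (quantile) binning is applied.
    """
    a = np.asarray(a)
    uniq = np.unique(a)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, a)
    edges = np.unique(np.quantile(a, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, a, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray,
                       bins: int = DEFAULT_BINS,
                       discrete: bool = False) -> float:
    """I(a; b) in nats from the plug-in estimate on the binned joint table."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("columns must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two samples")
    ca = a.astype(int) if discrete else discretize(a, bins)
    cb = b.astype(int) if discrete else discretize(b, bins)
    ca = np.searchsorted(np.unique(ca), ca)
    cb = np.searchsorted(np.unique(cb), cb)
    n = len(ca)
    table = np.zeros((ca.max() + 1, cb.max() + 1))
    np.add.at(table, (ca, cb), 1.0)
    pxy = table / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = float((pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])).sum())
    return max(mi, 0.0)
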