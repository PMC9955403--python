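"""Minimum-redundancy-maximum-relevance ranking by greedy MIQ forward search.

Selection order: (1) the most relevant feature; (2) any remaining feature
with nonzero relevance and zero redundancy against the selected set, most
relevant first; (3) greedy argmax of MIQ = relevance / mean-MI-redundancy;
(4) zero-relevance leftovers appended in seeded random order.
"""

from __future__ import annotations

import numpy as np

from ..types import WeightVector
from .mi import DEFAULT_BINS, discretize, mutual_information

__all__ = ["mrmr_rank"]

_ZERO = 1e-12


def mrmr_rank(X: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS,
              seed: int = 0) -> WeightVector:
    """Full MRMR ranking plus per-step scores.

    Weights are monotone in the selection order (``p - position``) so the
    ranking is recoverable from them; the per-step MIQ values (None for
    zero-redundancy picks, where the quotient is unbounded) live in
    ``meta['miq']``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)

    codes = [discretize(X[:, j], bins) for j in range(p)]
    ycode = discretize(y, bins)
    relevance = np.array([mutual_information(codes[j], ycode, discrete=True)
                          for j in range(p)])

    pair_cache: dict[tuple[int, int], float] = {}

    def pair_mi(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = mutual_information(codes[key[0]], codes[key[1]],
                                                 discrete=True)
        return pair_cache[key]

    def redundancy(j: int, S: list[int]) -> float:
        if not S:
            return 0.0
        return float(np.mean([pair_mi(j, z) for z in S]))

    S: list[int] = []
    miq_trace: list[float | None] = []
    remaining = set(range(p))

    # Step 1: most relevant feature.
    first = int(np.argmax(relevance))
    S.append(first)
    remaining.discard(first)
    miq_trace.append(None)

    # Step 2: relevant features with zero redundancy to the selected set.
    while True:
        zero_red = [j for j in remaining
                    if relevance[j] > _ZERO and redundancy(j, S) <= _ZERO]
        if not zero_red:
            break
        nxt = max(zero_red, key=lambda j: relevance[j])
        S.append(nxt)
        remaining.discard(nxt)
        miq_trace.append(None)

    # Step 3: greedy MIQ over the relevant remainder.
    while any(relevance[j] > _ZERO for j in remaining):
        best_j, best_q = -1, -np.inf
        for j in sorted(remaining):
            if relevance[j] <= _ZERO:
                continue
            red = redundancy(j, S)
            q = relevance[j] / red if red > _ZERO else np.inf
            if q > best_q:
                best_j, best_q = j, q
        S.append(best_j)
        remaining.discard(best_j)
        miq_trace.append(None if np.isinf(best_q) else float(best_q))

    # Step 4: zero-relevance leftovers in seeded random order.
    leftovers = sorted(remaining)
    if leftovers:
        order = rng.permutation(len(leftovers))
        for i in order:
            S.append(leftovers[i])
            miq_trace.append(None)

    ranking = np.asarray(S, dtype=int)
    weights = np.zeros(p)
    weights[ranking] = np.arange(p, 0, -1, dtype=float)
    return WeightVector(method="MRMR", weights=weights, ranking=ranking,
                        meta={"selection_order": ranking.tolist(),
                              "miq": miq_trace,
                              "relevance": relevance.tolist(),
                              "bins": bins, "seed": seed})
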