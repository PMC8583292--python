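"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (double loops, exhaustive enumeration) and
share no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def gi_star_brute(values: np.ndarray, cell_size: float, radius: float) -> np.ndarray:
    """Direct-summation Getis-Ord Gi* z on a grid with binary distance-band
    weights on cell centers (self-inclusive)."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    n = values.size
    xbar = values.sum() / n
    s = np.sqrt((values**2).sum() / n - xbar**2)
    z = np.zeros_like(values)
    for i in range(nrows):
        for j in range(ncols):
            wsum = 0.0
            wx = 0.0
            for a in range(nrows):
                for b in range(ncols):
                    d2 = ((a - i) * cell_size) ** 2 + ((b - j) * cell_size) ** 2
                    if d2 <= radius**2:
                        wsum += 1.0
                        wx += values[a, b]
            var = (n * wsum - wsum**2) / (n - 1)
            denom = s * np.sqrt(var) if var > 0 else 0.0
            z[i, j] = (wx - xbar * wsum) / denom if denom > 0 and s > 0 else 0.0
    return z


def auc_mann_whitney(truth, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic by pairwise loop,
    counting ties as one half."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def jenks_exhaustive(values, k: int):
    """Optimal 1-D partition into k contiguous classes by enumerating every
    split of the sorted values; returns (breaks, min_total_ssd)."""
    vals = sorted(values)
    n = len(vals)

    def ssd(chunk):
        m = sum(chunk) / len(chunk)
        return sum((v - m) ** 2 for v in chunk)

    best, best_breaks = None, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(ssd(vals[bounds[i]:bounds[i + 1]]) for i in range(k))
        if best is None or total < best - 1e-12:
            best, best_breaks = total, [vals[c - 1] for c in cuts]
    return best_breaks, best


def confusion_brute(truth, pred) -> dict:
    out = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for t, p in zip(truth, pred):
        key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
        out[key] += 1
    return out
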