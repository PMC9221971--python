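"""Independent brute-force oracles, deliberately naive.

Each function here re-derives a quantity the package computes, from first
principles and with explicit loops, so the tests compare two separately
written routes.  Nothing in this module imports from ``succinylome``.
"""

from __future__ import annotations

import math

import numpy as np


def naive_relative_quant(intensity: np.ndarray) -> np.ndarray:
    """Centralization then median normalization, written as plain loops.

    ``intensity``: rows = peptides, columns = samples, NaN = missing.
    """
    n_rows, n_cols = intensity.shape
    centered = np.full_like(intensity, np.nan)
    for j in range(n_rows):
        observed = [intensity[j, i] for i in range(n_cols) if not math.isnan(intensity[j, i])]
        mean = sum(observed) / len(observed)
        for i in range(n_cols):
            if not math.isnan(intensity[j, i]):
                centered[j, i] = intensity[j, i] / mean
    normalized = np.full_like(centered, np.nan)
    for i in range(n_cols):
        observed = sorted(
            centered[j, i] for j in range(n_rows) if not math.isnan(centered[j, i])
        )
        k = len(observed)
        median = (
            observed[k // 2] if k % 2 == 1 else (observed[k // 2 - 1] + observed[k // 2]) / 2.0
        )
        for j in range(n_rows):
            if not math.isnan(centered[j, i]):
                normalized[j, i] = centered[j, i] / median
    return normalized


def naive_fold_change(row: np.ndarray, treated_cols, control_cols) -> float:
    t = [row[i] for i in treated_cols if not math.isnan(row[i])]
    c = [row[i] for i in control_cols if not math.isnan(row[i])]
    return (sum(t) / len(t)) / (sum(c) / len(c))


def pooled_t_p_value(x, y) -> float:
    """Textbook equal-variance two-sample t-test, two-sided."""
    from scipy.stats import t as t_dist

    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    pooled_var = (ssx + ssy) / df
    se = math.sqrt(pooled_var * (1.0 / nx + 1.0 / ny))
    t_stat = (mx - my) / se
    return 2.0 * t_dist.sf(abs(t_stat), df)


def binomial_upper_tail(k: int, n: int, q: float) -> float:
    """P(X >= k) for X ~ Binomial(n, q), by explicit pmf summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * q**j * (1.0 - q) ** (n - j)
    return min(total, 1.0)


def hypergeom_upper_tail(a: int, n_universe: int, n_term: int, n_fg: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=n_universe, K=n_term, n=n_fg)."""
    denom = math.comb(n_universe, n_fg)
    total = 0.0
    upper = min(n_term, n_fg)
    for j in range(a, upper + 1):
        total += math.comb(n_term, j) * math.comb(n_universe - n_term, n_fg - j) / denom
    return min(total, 1.0)


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted p-values, hand-evaluated step-up."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def brute_force_alignment_score(
    a: str, b: str, substitution, gap_open: float = -10.0, gap_extend: float = -0.5
) -> float:
    """Optimal global affine-gap alignment score by enumerating every
    alignment path.  A gap of length L scores gap_open + (L-1)*gap_extend;
    gaps in the two sequences are separate runs.  Exponential: keep inputs
    short."""
    best = -math.inf

    def recurse(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, "M", score + substitution[a[i]][b[j]])
        if i < len(a):
            step = gap_extend if prev == "U" else gap_open
            recurse(i + 1, j, "U", score + step)
        if j < len(b):
            step = gap_extend if prev == "L" else gap_open
            recurse(i, j + 1, "L", score + step)

    recurse(0, 0, "", 0.0)
    return best
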