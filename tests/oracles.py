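"""Independent brute-force oracles, deliberately written element-by-element.

These re-derive, with plain Python loops and explicit run scanning, the
quantities the package computes with vectorized code: per-row linear
in-painting, normalized in-painting, circular-ROI statistics, weighted
kappa, and median/IQR.  They exist so oracle-equivalence tests never share
a code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def interp_rows_bruteforce(values: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Per-row linear in-painting by explicit scan over trace runs."""
    out = values.astype(float).copy()
    n_rows, n_cols = values.shape
    for i in range(n_rows):
        good_cols = [j for j in range(n_cols) if not trace[i, j]]
        if len(good_cols) == n_cols:
            continue
        if not good_cols:
            raise ValueError("row entirely trace")
        for j in range(n_cols):
            if not trace[i, j]:
                continue
            lefts = [g for g in good_cols if g < j]
            rights = [g for g in good_cols if g > j]
            if not lefts:
                out[i, j] = values[i, rights[0]]
            elif not rights:
                out[i, j] = values[i, lefts[-1]]
            else:
                x0, x1 = lefts[-1], rights[0]
                y0, y1 = values[i, x0], values[i, x1]
                out[i, j] = y0 + (j - x0) * (y1 - y0) / (x1 - x0)
    return out


def normalized_interp_bruteforce(
    original: np.ndarray, prior_proj: np.ndarray, trace: np.ndarray, floor: float
) -> np.ndarray:
    """Normalized in-painting: interpolate original/prior, multiply back."""
    pp = np.maximum(prior_proj, floor)
    ratio = original / pp
    filled = interp_rows_bruteforce(ratio, trace)
    out = original.astype(float).copy()
    for i in range(original.shape[0]):
        for j in range(original.shape[1]):
            if trace[i, j]:
                out[i, j] = filled[i, j] * pp[i, j]
    return out


def roi_stats_bruteforce(
    values: np.ndarray, center: tuple[float, float], radius_px: float
) -> tuple[float, float, int]:
    """Mean / population SD / count over pixel centers inside the circle."""
    pixels = []
    for r in range(values.shape[0]):
        for c in range(values.shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius_px**2:
                pixels.append(values[r, c])
    arr = np.array(pixels)
    return float(arr.mean()), float(arr.std(ddof=0)), len(pixels)


def weighted_kappa_bruteforce(table: np.ndarray) -> float:
    """Weighted kappa by explicit double sums over the contingency table."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    n = table.sum()
    p_o = 0.0
    p_e = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - abs(i - j) / (k - 1)
            p_o += w * table[i, j] / n
            p_e += w * (table[i].sum() / n) * (table[:, j].sum() / n)
    return (p_o - p_e) / (1.0 - p_e)


def median_iqr_bruteforce(values) -> tuple[float, float]:
    """Median and Q3-Q1 from sorted order statistics, linear interpolation."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def quantile(q: float) -> float:
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        frac = pos - lo
        return v[lo] * (1 - frac) + v[hi] * frac

    return quantile(0.5), quantile(0.75) - quantile(0.25)
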