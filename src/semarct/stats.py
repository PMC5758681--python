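"""Paired nonparametric comparison and inter-reader agreement.

Implements the Wilcoxon signed-rank test (exact by enumeration of all sign
assignments for small samples, normal approximation with tie correction
otherwise), linearly weighted Cohen's kappa with a large-sample 95%
confidence interval, and median / interquartile-range summaries.

The signed-rank test is hand-implemented rather than delegated because the
exact path must enumerate sign assignments under mid-ranked ties, which the
usual library routines decline; library implementations serve as
cross-check oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX_N = 12  # enumeration of 2^n sign patterns stays trivial up to here


@dataclass(frozen=True)
class PairedSample:
    """Matched (standard, mar) measurements per ROI/vessel."""

    standard: np.ndarray
    mar: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.standard, dtype=float)
        b = np.asarray(self.mar, dtype=float)
        object.__setattr__(self, "standard", a)
        object.__setattr__(self, "mar", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired sample needs two equal-length 1-D arrays")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired sample contains non-finite values")

    @property
    def differences(self) -> np.ndarray:
        return self.mar - self.standard


@dataclass(frozen=True)
class AgreementSample:
    """Two readers' ordinal scores in {1..5}; linear disagreement weights."""

    reader1: np.ndarray
    reader2: np.ndarray
    n_categories: int = 5

    def __post_init__(self) -> None:
        r1 = np.asarray(self.reader1, dtype=int)
        r2 = np.asarray(self.reader2, dtype=int)
        object.__setattr__(self, "reader1", r1)
        object.__setattr__(self, "reader2", r2)
        if r1.shape != r2.shape or r1.ndim != 1 or r1.size < 2:
            raise ValueError("need two equal-length score vectors with n >= 2")
        for r in (r1, r2):
            if r.min() < 1 or r.max() > self.n_categories:
                raise ValueError(f"scores must lie in 1..{self.n_categories}")


def wilcoxon_signed_rank(
    sample: PairedSample, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  Returns ``(W, p)`` with ``W = min(T+, T-)``.

    ``mode='exact'`` enumerates all ``2^n`` sign assignments (valid with
    ties); ``'approx'`` uses the normal approximation with tie correction;
    ``'auto'`` picks exact for n <= 12 nonzero differences.
    """
    if mode not in ("exact", "approx", "auto"):
        raise ValueError("mode must be exact, approx, or auto")
    d = sample.differences
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = rankdata(np.abs(d))  # mid-ranks for ties
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    w = min(t_plus, t_minus)

    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_N else "approx"

    if mode == "exact":
        # distribution of T+ over all sign assignments, uniform under H0
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        t_all = signs @ ranks
        p_le = np.mean(t_all <= t_plus + 1e-12)
        p_ge = np.mean(t_all >= t_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        # tie correction subtracts sum(t^3 - t)/48 from the null variance
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((counts**3 - counts).sum()) / 48.0
        )
        if var <= 0:
            raise ValueError("degenerate variance in normal approximation")
        z = (t_plus - mean) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return w, float(p)


def weighted_kappa(sample: AgreementSample) -> tuple[float, float, float]:
    """Linearly weighted Cohen's kappa with an asymptotic 95% CI.

    Agreement weights on the k x k table are ``w_ij = 1 - |i - j| / (k - 1)``;
    kappa = (p_o - p_e) / (1 - p_e) with weighted observed and chance
    agreement.  The CI uses the large-sample standard error of
    Fleiss, Cohen & Everitt.
    """
    k = sample.n_categories
    table = np.zeros((k, k), dtype=float)
    for a, b in zip(sample.reader1, sample.reader2):
        table[a - 1, b - 1] += 1.0
    return weighted_kappa_from_table(table)


def weighted_kappa_from_table(table: np.ndarray) -> tuple[float, float, float]:
    """Weighted kappa and 95% CI from a square contingency table of counts."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("contingency table must be square")
    k = table.shape[0]
    n = table.sum()
    if n < 2:
        raise ValueError("need at least 2 rated items")
    p = table / n
    i, j = np.mgrid[0:k, 0:k]
    w = 1.0 - np.abs(i - j) / (k - 1)

    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError(
            "chance agreement is 1 (both readers constant at the same "
            "category); kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt large-sample variance of weighted kappa
    w_row = (w * col[None, :]).sum(axis=1)  # E_j[w_ij] over reader-2 marginal
    w_col = (w * row[:, None]).sum(axis=0)  # E_i[w_ij] over reader-1 marginal
    term = w - (w_row[:, None] + w_col[None, :]) * (1.0 - kappa)
    var = (
        float((p * term**2).sum()) - (kappa - p_e * (1.0 - kappa)) ** 2
    ) / (n * (1.0 - p_e) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return float(kappa), float(kappa - 1.96 * se), float(kappa + 1.96 * se)


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1).

    Quantiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median of an empty sample is undefined")
    if not np.all(np.isfinite(v)):
        raise ValueError("sample contains non-finite values")
    q1, q3 = np.percentile(v, [25.0, 75.0], method="linear")
    return float(np.median(v)), float(q3 - q1)
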