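"""Exact and asymptotic statistical kernels.

Every test used downstream (Wilcoxon signed-rank, Mann-Whitney U,
two-sample Kolmogorov-Smirnov, Fisher exact, paired t, Benjamini-Hochberg
adjustment) is implemented here so the exact code paths can be validated
against enumeration oracles.  SciPy is used only for distribution
functions (normal/t CDFs), never for the tests themselves.

Exact p-values are computed by full enumeration below documented size
bounds (2^n sign patterns for the signed-rank test, rank-set enumeration
for Mann-Whitney, hypergeometric sums for Fisher); above the bounds the
standard normal approximations with continuity and tie corrections apply.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

Z_95 = 1.959964  # two-sided 95% normal quantile

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    alternative: str = "two_sided"
    exact: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p outside [0,1]: {self.p}")


def _check_alternative(alternative: str) -> str:
    alt = alternative.replace("-", "_")
    if alt not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    return alt


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j < len(sv) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)
        i = j
    return ranks


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(diffs, alternative: str = "two_sided",
                         exact_limit: int = 25) -> TestResult:
    """Signed-rank test of symmetry of ``diffs`` about zero.

    Zero differences are dropped (zeros-excluded convention).  For
    n <= ``exact_limit`` the null distribution of W+ is enumerated over
    all 2^n sign patterns (a convolution over doubled midranks, so ties
    are handled exactly); above that a normal approximation with tie
    correction and continuity correction is used.
    """
    alt = _check_alternative(alternative)
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    n_zero = len(d) - len(nz)
    if n_zero:
        warnings.warn(f"dropping {n_zero} zero difference(s)")
    n = len(nz)
    if n == 0:
        warnings.warn("all differences are zero; p = 1")
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", alt, True)

    ranks = _midranks(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())

    if n <= exact_limit:
        # doubled ranks are integers even with midranks
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum()
        p_le = counts[: w2 + 1].sum()
        if alt == "greater":
            p = p_ge
        elif alt == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(w_plus, float(min(p, 1.0)),
                          "wilcoxon_signed_rank", alt, True)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction over groups of tied |d|
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    sd = math.sqrt(var)
    z_g = (w_plus - mean - 0.5) / sd
    z_l = (w_plus - mean + 0.5) / sd
    p_ge = float(special.ndtr(-z_g))
    p_le = float(special.ndtr(z_l))
    if alt == "greater":
        p = p_ge
    elif alt == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(w_plus, p, "wilcoxon_signed_rank", alt, False)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_exact_tail(u_obs: float, n: int, m: int, x: np.ndarray,
                    y: np.ndarray):
    """Null distribution of U by enumerating which ranks belong to x."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    N = n + m
    us = []
    for idx in combinations(range(N), n):
        rx = ranks[list(idx)].sum()
        us.append(rx - n * (n + 1) / 2.0)
    us = np.asarray(us)
    eps = 1e-9
    p_ge = float((us >= u_obs - eps).mean())
    p_le = float((us <= u_obs + eps).mean())
    return p_ge, p_le


def mann_whitney_u(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U test; ``alternative='greater'`` means x tends larger.

    Exact enumeration is used when min(n,m) <= 8, n+m <= 24 and there are
    no ties across the pooled sample; otherwise the normal approximation
    with midrank tie correction and continuity correction.
    """
    alt = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    has_ties = len(np.unique(pooled)) < n + m
    if min(n, m) <= 8 and n + m <= 24 and not has_ties:
        p_ge, p_le = _mwu_exact_tail(u, n, m, x, y)
        if alt == "greater":
            p = p_ge
        elif alt == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(u, p, "mann_whitney_u", alt, True)

    N = n + m
    mean = n * m / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        warnings.warn("degenerate pooled sample (all values tied); p = 1")
        return TestResult(u, 1.0, "mann_whitney_u", alt, False)
    sd = math.sqrt(var)
    p_ge = float(special.ndtr(-(u - mean - 0.5) / sd))
    p_le = float(special.ndtr((u - mean + 0.5) / sd))
    if alt == "greater":
        p = p_ge
    elif alt == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(u, p, "mann_whitney_u", alt, False)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov (two-sample)
# ---------------------------------------------------------------------------

def ks_two_sample(x, y) -> TestResult:
    """Two-sample KS: D statistic plus the asymptotic (Stephens) p-value."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n
    cdf_y = np.searchsorted(y, grid, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    en = math.sqrt(n * m / (n + m))
    lam = (en + 0.12 + 0.11 / en) * d
    # Kolmogorov asymptotic survival function
    if lam < 1e-3:
        p = 1.0
    else:
        terms = [(-1) ** (k - 1) * math.exp(-2.0 * (k * lam) ** 2)
                 for k in range(1, 101)]
        p = min(1.0, max(0.0, 2.0 * sum(terms)))
    return TestResult(d, p, "ks_two_sample", "two_sided", False)


# ---------------------------------------------------------------------------
# Fisher exact (2x2)
# ---------------------------------------------------------------------------

def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P[X = k] for X ~ Hypergeom(N population, K successes, n draws)."""
    if k < max(0, n + K - N) or k > min(K, n):
        return 0.0
    return math.exp(_lchoose(K, k) + _lchoose(N - K, n - k) - _lchoose(N, n))


def fisher_exact_2x2(table, alternative: str = "two_sided") -> TestResult:
    """Fisher exact test on [[a, b], [c, d]].

    ``greater`` tests enrichment of the top-left cell.  Two-sided p is the
    sum of table probabilities no larger than the observed one (standard
    convention).  Returns the sample odds ratio as the statistic
    (inf/nan-safe).
    """
    alt = _check_alternative(alternative)
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + b       # row-1 margin
    n = a + c       # col-1 margin
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        warnings.warn("degenerate 2x2 margin; p = 1")
        odds = math.nan
        return TestResult(odds, 1.0, "fisher_exact", alt, True)

    lo = max(0, n + K - N)
    hi = min(K, n)
    pmf = np.array([_hypergeom_pmf(k, K, n, N) for k in range(lo, hi + 1)])
    idx = a - lo
    p_obs = pmf[idx]
    p_ge = float(pmf[idx:].sum())
    p_le = float(pmf[: idx + 1].sum())
    if alt == "greater":
        p = p_ge
    elif alt == "less":
        p = p_le
    else:
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(odds, min(1.0, p), "fisher_exact", alt, True)


# ---------------------------------------------------------------------------
# Paired t
# ---------------------------------------------------------------------------

def paired_t(x, y, alternative: str = "two_sided") -> TestResult:
    """Paired Student's t test on matched samples x, y (tests mean(x-y)=0).

    Degenerate inputs follow explicit conventions: identical pairs give
    t=0, p=1; a constant non-zero difference gives p=0.
    """
    alt = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(0.0, 1.0, "paired_t", alt, False)
        t = math.inf if mean > 0 else -math.inf
        p_ge, p_le = (0.0, 1.0) if mean > 0 else (1.0, 0.0)
    else:
        t = mean / (sd / math.sqrt(n))
        p_le = float(special.stdtr(n - 1, t))
        p_ge = 1.0 - p_le
    if alt == "greater":
        p = p_ge
    elif alt == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(t, p, "paired_t", alt, False)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """BH step-up FDR adjustment (monotone-enforced, capped at 1).

    NaNs are passed through and do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0,1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out
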