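"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths of the package: the Fisher oracle
enumerates tables with exact rational arithmetic; the dense oracle applies
the two-sided point-probability rule by explicit pairwise comparison; the
arc-statistic oracle scans every boundary pair with plain Python loops.
"""

from fractions import Fraction
from math import comb, sqrt

import numpy as np
from scipy.stats import hypergeom

TIE_EPS = 1e-7


def fisher_oracle_exact(n_ref, n_alt, t_ref, t_alt) -> float:
    """Two-sided Fisher p by exact rational enumeration over the margins."""
    r1, r2 = n_ref + n_alt, t_ref + t_alt
    c1 = n_ref + t_ref
    n = r1 + r2
    denom = comb(n, r1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    pmf = {k: Fraction(comb(c1, k) * comb(n - c1, r1 - k), denom) for k in range(kmin, kmax + 1)}
    p0 = pmf[n_ref]
    cutoff = p0 * (Fraction(10**7 + 1, 10**7))  # p0 * (1 + 1e-7), exactly
    return float(min(sum(p for p in pmf.values() if p <= cutoff), Fraction(1)))


def fisher_oracle_dense_grid(r1: int, r2: int):
    """Two-sided p for every table with row margins (r1, r2).

    Returns an array P of shape (r1 + 1, r1 + r2 + 1) indexed by
    (k = top-left cell, c1 = first-column margin); entries outside the
    support are NaN.  The pmf comes from scipy's hypergeometric
    distribution; the tail rule is applied by dense pairwise comparison.
    """
    n = r1 + r2
    k = np.arange(r1 + 1)
    c1 = np.arange(n + 1)
    pmf = hypergeom.pmf(k[:, None], n, c1[None, :], r1)  # (k, c1)
    support = pmf > 0
    # include[c, i, j]: table j is at least as extreme as table i (column c)
    pmf_t = pmf.T  # (c1, k)
    include = pmf_t[:, None, :] <= pmf_t[:, :, None] * (1.0 + TIE_EPS)
    p = np.einsum("cij,cj->ci", include, pmf_t).T  # back to (k, c1)
    p = np.minimum(p, 1.0)
    p[~support] = np.nan
    return p


def max_t_bruteforce(x, min_pts=2):
    """Exhaustive (i, j) scan of the standardized arc statistic.

    Plain-Python double loop; ties broken toward smallest i then smallest j.
    Returns (t, i, j) or None.
    """
    x = list(map(float, x))
    n = len(x)
    if n < 2 * min_pts:
        return None
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    if var == 0:
        return None
    s = sqrt(var)
    best = None
    for i in range(0, n):
        if i != 0 and i < min_pts:
            continue
        for j in range(i + min_pts, n + 1):
            m = j - i
            if m > n - min_pts:
                continue
            if j != n and n - j < min_pts:
                continue
            arc = x[i:j]
            rest = x[:i] + x[j:]
            t = abs(sum(arc) / m - sum(rest) / len(rest)) / (s * sqrt(1 / m + 1 / len(rest)))
            if best is None or t > best[0] * (1 + 1e-9):
                best = (t, i, j)
    return best


def percentile_linear(values, q):
    """Sort-and-interpolate empirical percentile (linear between order stats)."""
    v = sorted(float(x) for x in values)
    if len(v) == 1:
        return v[0]
    rank = (len(v) - 1) * q / 100.0
    lo = int(rank)
    frac = rank - lo
    if lo + 1 >= len(v):
        return v[-1]
    return v[lo] * (1 - frac) + v[lo + 1] * frac
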