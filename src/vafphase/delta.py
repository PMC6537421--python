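"""Per-site VAF, ΔVAF, and the two-sided Fisher exact test.

ΔVAF = tumor VAF − normal VAF.  In a region where one homolog gained or lost
copies in the tumor, heterozygous germline variants shift away from VAF 0.5
with a sign determined by which homolog carries the alternate allele; the
Fisher exact test on the 2×2 table of (ref, alt) counts in (normal, tumor)
gates which individual sites shift more than read sampling noise allows.

The two-sided p-value follows the standard point-probability rule: the sum of
hypergeometric probabilities of all tables (with the observed margins) whose
point probability is at most that of the observed table, with a relative tie
tolerance of 1e-7.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .model import VariantSite

#: relative tolerance when comparing point probabilities for the two-sided sum
_TIE_REL_TOL = 1e-7

DEFAULT_FISHER_ALPHA = 0.05


@dataclass(frozen=True)
class DeltaVAFResult:
    """VAFs, ΔVAF and Fisher significance for one site."""

    site: VariantSite
    vaf_normal: float
    vaf_tumor: float
    dvaf: float
    abs_dvaf: float
    p_value: float
    significant: bool


def compute_vaf(ref_count: int, alt_count: int) -> float:
    """Variant allele frequency alt/(ref+alt); requires depth >= 1."""
    depth = ref_count + alt_count
    if depth < 1:
        raise ValueError("cannot compute VAF at zero depth")
    return alt_count / depth


def _log_factorials(n: int) -> np.ndarray:
    return gammaln(np.arange(n + 1) + 1.0)


def _support_pmf(r1: int, r2: int, c1: int, lf: np.ndarray) -> tuple[int, np.ndarray]:
    """Hypergeometric pmf over the support of k = top-left cell.

    Margins: row sums (r1, r2), first column sum c1, total N = r1 + r2.
    Returns (kmin, pmf over k = kmin..kmax).
    """
    n_total = r1 + r2
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        lf[c1] - lf[k] - lf[c1 - k]
        + lf[n_total - c1] - lf[r1 - k] - lf[n_total - c1 - (r1 - k)]
        - (lf[n_total] - lf[r1] - lf[r2])
    )
    return kmin, np.exp(logpmf)


def _two_sided_from_pmf(pmf: np.ndarray) -> np.ndarray:
    """Two-sided p for every point of the support, via sorted cumulative sums."""
    order = np.argsort(pmf, kind="stable")
    sp = pmf[order]
    cs = np.cumsum(sp)
    idx = np.searchsorted(sp, pmf * (1.0 + _TIE_REL_TOL), side="right") - 1
    return np.minimum(cs[idx], 1.0)


def fisher_exact_two_sided(n_ref: int, n_alt: int, t_ref: int, t_alt: int) -> float:
    """Exact two-sided Fisher p for the table [[n_ref, n_alt], [t_ref, t_alt]]."""
    for v in (n_ref, n_alt, t_ref, t_alt):
        if v < 0:
            raise ValueError("counts must be non-negative")
    r1, r2 = n_ref + n_alt, t_ref + t_alt
    if r1 < 1 or r2 < 1:
        raise ValueError("each sample must have depth >= 1")
    c1 = n_ref + t_ref
    if c1 == 0 or c1 == r1 + r2:
        return 1.0  # single admissible table
    lf = _log_factorials(r1 + r2)
    kmin, pmf = _support_pmf(r1, r2, c1, lf)
    return float(_two_sided_from_pmf(pmf)[n_ref - kmin])


def fisher_pvalues_for_margins(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-sided p-values for *all* tables with row margins (r1, r2) and
    first-column margin c1, indexed by the support of the top-left cell
    (k = max(0, c1-r2) .. min(r1, c1)).  Vectorized batch form of
    :func:`fisher_exact_two_sided`.
    """
    lf = _log_factorials(r1 + r2)
    _, pmf = _support_pmf(r1, r2, c1, lf)
    return _two_sided_from_pmf(pmf)


def compute_delta_vaf(site: VariantSite, alpha: float = DEFAULT_FISHER_ALPHA) -> DeltaVAFResult:
    """VAFs, ΔVAF and Fisher test for one site (both depths must be >= 1)."""
    vaf_n = compute_vaf(site.n_ref, site.n_alt)
    vaf_t = compute_vaf(site.t_ref, site.t_alt)
    dvaf = vaf_t - vaf_n
    p = fisher_exact_two_sided(site.n_ref, site.n_alt, site.t_ref, site.t_alt)
    return DeltaVAFResult(
        site=site,
        vaf_normal=vaf_n,
        vaf_tumor=vaf_t,
        dvaf=dvaf,
        abs_dvaf=abs(dvaf),
        p_value=p,
        significant=p < alpha,
    )


def compute_delta_vafs(
    sites: Iterable[VariantSite], alpha: float = DEFAULT_FISHER_ALPHA
) -> list[DeltaVAFResult]:
    return [compute_delta_vaf(s, alpha) for s in sites]


def flag_significant(
    results: Sequence[DeltaVAFResult], alpha: float
) -> list[DeltaVAFResult]:
    """Re-flag results at a new alpha (strict inequality, no correction)."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    return [dataclasses.replace(r, significant=r.p_value < alpha) for r in results]
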