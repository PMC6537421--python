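"""Circular binary segmentation of absolute ΔVAF profiles.

Each chromosome's heterozygous sites are first partitioned at large
inter-site gaps (the smoothing parameter, default 1 Mb): gaps at least
``min_length`` bp wide are forced breakpoints, so raising ``min_length``
joins more distant sites into common segmentation units and yields longer
segments.

Within a unit, recursive CBS is applied to the absolute ΔVAF values: the
change-point statistic is the maximum over all arc boundaries i < j of

    T(i, j) = |mean(x[i:j]) − mean(rest)| / (s · sqrt(1/n_arc + 1/n_rest))

where s is the standard deviation of the whole stretch.  Significance of the
maximal T is assessed by permutation; if p < alpha the stretch is split at
the best boundary pair and the pieces are re-segmented, otherwise the stretch
is emitted as one segment.  Splits that would create a segment with fewer
than ``min_seg_points`` sites are not eligible.  Given the same seed the
output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

DEFAULT_MIN_LENGTH_BP = 1_000_000
DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_ALPHA_SPLIT = 0.01
DEFAULT_MIN_SEG_POINTS = 2
DEFAULT_SEED = 17

#: relative tolerance for ties in the arc-statistic argmax
_T_REL_TOL = 1e-9
#: permutation batch size (permutations are consumed in deterministic order,
#: with early stopping once the split can no longer reach significance)
_PERM_BATCH = 250


@dataclass
class CBSParams:
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    alpha_split: float = DEFAULT_ALPHA_SPLIT
    min_seg_points: int = DEFAULT_MIN_SEG_POINTS
    seed: int = DEFAULT_SEED


@dataclass
class SegmentationUnit:
    """A gap-delimited chunk of one chromosome's abs ΔVAF profile."""

    chrom: str
    positions: np.ndarray  # bp, strictly increasing
    values: np.ndarray  # abs ΔVAF per site
    site_indices: np.ndarray  # caller-side indices of the member sites

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("unit positions must be strictly increasing")


@dataclass
class Segment:
    """A run of sites with similar abs ΔVAF, spanning first to last member."""

    chrom: str
    start: int
    end: int
    member_indices: np.ndarray
    n_variants: int = 0
    mean_abs_dvaf: float = float("nan")
    size_bp: int = 0
    eligible: bool = False
    significant: Optional[bool] = None
    null_model: Optional[str] = None

    @property
    def segment_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# gap smoothing
# ---------------------------------------------------------------------------

def find_large_gaps(positions: Sequence[int], min_length: int) -> list[int]:
    """Indices i such that a forced breakpoint falls between site i and i+1.

    A breakpoint is forced wherever pos[i+1] − pos[i] >= min_length.
    """
    if min_length <= 0:
        raise ValueError("min_length must be > 0")
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be sorted strictly ascending")
    return [int(i) for i in np.flatnonzero(np.diff(pos) >= min_length)]


def split_into_units(
    chrom: str,
    positions: Sequence[int],
    values: Sequence[float],
    site_indices: Sequence[int],
    min_length: int = DEFAULT_MIN_LENGTH_BP,
) -> list[SegmentationUnit]:
    """Partition a chromosome's sites into gap-delimited segmentation units."""
    pos = np.asarray(positions, dtype=np.int64)
    val = np.asarray(values, dtype=float)
    idx = np.asarray(site_indices, dtype=np.int64)
    if pos.size == 0:
        return []
    breaks = find_large_gaps(pos, min_length)
    bounds = [0] + [b + 1 for b in breaks] + [pos.size]
    return [
        SegmentationUnit(chrom, pos[a:b], val[a:b], idx[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# arc statistic
# ---------------------------------------------------------------------------

def _valid_start_mask(n: int, m: int, min_pts: int) -> np.ndarray:
    """Eligibility of arc start i for arc length m: every non-empty resulting
    piece ([0:i], [i:i+m], [i+m:n]) must have >= min_pts sites."""
    i = np.arange(n - m + 1)
    j = i + m
    return ((i == 0) | (i >= min_pts)) & ((j == n) | (n - j >= min_pts))


def max_arc_statistic(
    values: np.ndarray, min_pts: int = DEFAULT_MIN_SEG_POINTS
) -> Optional[tuple[float, int, int]]:
    """Exhaustive scan for the maximal standardized arc statistic.

    Returns (T_max, i, j) for the best arc values[i:j], or None when no
    eligible split exists or the stretch has zero variance.  Ties are broken
    toward the smallest left boundary, then the smallest right boundary.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_pts:
        return None
    s = float(x.std(ddof=1))
    if s == 0.0:
        return None
    cs = np.concatenate(([0.0], np.cumsum(x)))
    total = cs[-1]
    best_t, best_ij = -np.inf, None
    for m in range(min_pts, n - min_pts + 1):
        valid = _valid_start_mask(n, m, min_pts)
        if not valid.any():
            continue
        w = cs[m:] - cs[:-m]
        n2 = n - m
        t = np.abs(w / m - (total - w) / n2) / (s * math.sqrt(1.0 / m + 1.0 / n2))
        t = np.where(valid, t, -np.inf)
        tmax = float(t.max())
        if not np.isfinite(tmax):
            continue
        # smallest i among near-ties (complementary arcs give equal T up to
        # floating-point noise)
        k = int(np.flatnonzero(t >= tmax * (1.0 - _T_REL_TOL))[0])
        tk = tmax
        if tk > best_t * (1.0 + _T_REL_TOL):
            best_t, best_ij = tk, (k, k + m)
        elif best_ij is not None and tk >= best_t * (1.0 - _T_REL_TOL):
            if (k, k + m) < best_ij:
                best_ij = (k, k + m)
    if best_ij is None or not np.isfinite(best_t):
        return None
    return best_t, best_ij[0], best_ij[1]


def _batch_max_arc_statistic(rows: np.ndarray, min_pts: int) -> np.ndarray:
    """Max arc statistic per row of a (batch × n) matrix.

    All rows are permutations of the same values, so the stretch standard
    deviation is shared.
    """
    b, n = rows.shape
    s = float(rows[0].std(ddof=1))
    cs = np.concatenate((np.zeros((b, 1)), np.cumsum(rows, axis=1)), axis=1)
    total = cs[:, -1:]
    best = np.full(b, -np.inf)
    for m in range(min_pts, n - min_pts + 1):
        valid = _valid_start_mask(n, m, min_pts)
        if not valid.any():
            continue
        w = cs[:, m:] - cs[:, :-m]
        n2 = n - m
        t = np.abs(w / m - (total - w) / n2) / (s * math.sqrt(1.0 / m + 1.0 / n2))
        t[:, ~valid] = -np.inf
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _permutation_pvalue(
    values: np.ndarray, t_obs: float, params: CBSParams, rng: np.random.Generator
) -> float:
    """Permutation p for the observed max arc statistic.

    Permutations are drawn in deterministic batches; once the exceedance
    count guarantees p >= alpha_split the scan stops early (the returned
    lower bound preserves the split/no-split decision).
    """
    n_perm = params.n_permutations
    stop_count = math.ceil(params.alpha_split * n_perm)
    count = done = 0
    while done < n_perm:
        b = min(_PERM_BATCH, n_perm - done)
        perm = rng.permuted(np.broadcast_to(values, (b, values.size)), axis=1)
        count += int((_batch_max_arc_statistic(perm, params.min_seg_points) >= t_obs).sum())
        done += b
        if count >= stop_count:
            return max(count / n_perm, params.alpha_split)
    return count / n_perm


# ---------------------------------------------------------------------------
# recursive segmentation
# ---------------------------------------------------------------------------

def _segment_recursive(
    values: np.ndarray,
    offset: int,
    params: CBSParams,
    rng: np.random.Generator,
    out: list[tuple[int, int]],
) -> None:
    scan = max_arc_statistic(values, params.min_seg_points)
    if scan is not None:
        t_obs, i, j = scan
        p = _permutation_pvalue(values, t_obs, params, rng)
        if p < params.alpha_split:
            for a, b in ((0, i), (i, j), (j, values.size)):
                if b > a:
                    _segment_recursive(values[a:b], offset + a, params, rng, out)
            return
    out.append((offset, offset + values.size))


def cbs_segment(
    unit: SegmentationUnit,
    params: Optional[CBSParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Segment]:
    """Segment one unit into runs of constant mean abs ΔVAF.

    The emitted segments are contiguous, non-overlapping, ordered, and
    jointly cover all unit sites.  Deterministic given ``params.seed`` (or an
    explicitly supplied generator).
    """
    params = params or CBSParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if unit.values.size == 0:
        return []
    spans: list[tuple[int, int]] = []
    _segment_recursive(unit.values, 0, params, rng, spans)
    spans.sort()
    segments = [
        Segment(
            chrom=unit.chrom,
            start=int(unit.positions[a]),
            end=int(unit.positions[b - 1]),
            member_indices=unit.site_indices[a:b].copy(),
        )
        for a, b in spans
    ]
    return summarize_segments(segments, unit)


def summarize_segments(segments: list[Segment], unit: SegmentationUnit) -> list[Segment]:
    """Fill n_variants, mean abs ΔVAF, size and eligibility per segment.

    Segments with a single member variant are ineligible for significance
    testing (a mean over one noisy site is uninformative).
    """
    lookup = {int(i): float(v) for i, v in zip(unit.site_indices, unit.values)}
    for seg in segments:
        if seg.member_indices.size == 0:
            raise ValueError("segment with empty member list")
        vals = [lookup[int(i)] for i in seg.member_indices]
        seg.n_variants = len(vals)
        seg.mean_abs_dvaf = float(np.mean(vals))
        seg.size_bp = seg.end - seg.start + 1
        seg.eligible = seg.n_variants > 1
    return segments


def segment_chromosome(
    chrom: str,
    positions: Sequence[int],
    values: Sequence[float],
    site_indices: Sequence[int],
    min_length: int = DEFAULT_MIN_LENGTH_BP,
    params: Optional[CBSParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Segment]:
    """Gap-split then CBS-segment one chromosome's abs ΔVAF profile."""
    params = params or CBSParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []
    for unit in split_into_units(chrom, positions, values, site_indices, min_length):
        segments.extend(cbs_segment(unit, params, rng))
    return segments
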