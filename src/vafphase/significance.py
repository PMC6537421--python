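"""Decide which segments represent true somatic copy-number alterations.

Three interchangeable rules:

* hard cutoff — a segment is significant when its mean absolute ΔVAF is at
  least 0.14.  That default corresponds to the empirical 95th percentile of
  segment means observed in duplicated normal:normal pairs, i.e. an expected
  ~5% false-call rate from read sampling noise alone; it is exposed as a
  parameter rather than re-derived.
* region-specific — the segment mean is compared to the empirical
  distribution of means of the *same genomic region* across a panel of
  duplicated normal:normal pairs, accounting for region-specific sampling
  noise; significant at or above the 90th percentile.
* fold change — for externally segmented copy-ratio records, significant
  when the fold change is below 0.9 or above 1.1 (a single-chromosome loss
  or gain in 20% of tumor cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import delta as _delta
from .cbs import CBSParams, Segment, segment_chromosome
from .model import ExternalSegment, VafPhaseError, VariantSite

logger = logging.getLogger("vafphase")

DEFAULT_HARD_CUTOFF = 0.14
DEFAULT_NULL_PERCENTILE = 90.0
DEFAULT_FC_LOW = 0.9
DEFAULT_FC_HIGH = 1.1

#: contamination screen for null-panel pairs: a pair is excluded when any of
#: its segments looks like a real CNA (many variants, strong mean shift)
SCREEN_MIN_VARIANTS = 20
SCREEN_MIN_MEAN_ABS_DVAF = 0.25

VERDICT_SIGNIFICANT = "significant"
VERDICT_NOT_SIGNIFICANT = "not_significant"
VERDICT_INELIGIBLE = "ineligible"
VERDICT_NO_NULL_COVERAGE = "no_null_coverage"


class EmptyPanelError(VafPhaseError):
    """No usable normal:normal pairs remain after the contamination screen."""


def hard_cutoff_test(segment: Segment, cutoff: float = DEFAULT_HARD_CUTOFF) -> str:
    """Significant iff mean abs ΔVAF >= cutoff (inclusive)."""
    if not segment.eligible:
        segment.significant = None
        segment.null_model = "hard_cutoff"
        return VERDICT_INELIGIBLE
    segment.significant = bool(segment.mean_abs_dvaf >= cutoff)
    segment.null_model = "hard_cutoff"
    return VERDICT_SIGNIFICANT if segment.significant else VERDICT_NOT_SIGNIFICANT


@dataclass
class PanelPair:
    """Per-site abs ΔVAF of one normal:normal replicate pair, by position."""

    chroms: np.ndarray
    positions: np.ndarray
    abs_dvaf: np.ndarray

    def region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        mask = (self.chroms == chrom) & (self.positions >= start) & (self.positions <= end)
        return self.abs_dvaf[mask]


@dataclass
class NullPanel:
    """A screened panel of duplicated-normal pairs, indexable by interval."""

    pairs: list[PanelPair]

    def __len__(self) -> int:
        return len(self.pairs)

    def region_means(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Mean abs ΔVAF per pair over the interval; pairs without
        overlapping sites are skipped."""
        means = [
            float(v.mean())
            for p in self.pairs
            if (v := p.region_values(chrom, start, end)).size > 0
        ]
        return np.asarray(means, dtype=float)

    def pooled_region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        vals = [p.region_values(chrom, start, end) for p in self.pairs]
        return np.concatenate(vals) if vals else np.empty(0)


def build_null_panel(
    pairs: Sequence[Sequence[VariantSite]],
    cbs_params: Optional[CBSParams] = None,
    min_length: int = 1_000_000,
) -> NullPanel:
    """Build the region-specific null from normal:normal replicate pairs.

    One normal of each pair occupies the tumor count slots, so the per-site
    abs ΔVAF measures pure read sampling noise.  Pairs whose VAF-CBS profile
    contains a CNA-like segment (>= 20 variants with mean abs ΔVAF >= 0.25)
    are excluded as suspected contamination.
    """
    if len(pairs) == 0:
        raise EmptyPanelError("no normal:normal pairs supplied")
    cbs_params = cbs_params or CBSParams()
    kept: list[PanelPair] = []
    for pair_idx, sites in enumerate(pairs):
        sites = sorted(sites, key=lambda s: (s.chrom, s.pos))
        results = _delta.compute_delta_vafs(sites)
        chroms = np.array([s.chrom for s in sites], dtype=object)
        positions = np.array([s.pos for s in sites], dtype=np.int64)
        absd = np.array([r.abs_dvaf for r in results], dtype=float)
        contaminated = False
        for chrom in dict.fromkeys(chroms):
            m = chroms == chrom
            segs = segment_chromosome(
                str(chrom), positions[m], absd[m], np.flatnonzero(m),
                min_length=min_length, params=cbs_params,
            )
            if any(
                s.n_variants >= SCREEN_MIN_VARIANTS
                and s.mean_abs_dvaf >= SCREEN_MIN_MEAN_ABS_DVAF
                for s in segs
            ):
                contaminated = True
                break
        if contaminated:
            logger.warning(
                "build_null_panel: excluding pair %d (CNA-like signal, suspected "
                "contamination)", pair_idx,
            )
            continue
        kept.append(PanelPair(chroms, positions, absd))
    if not kept:
        raise EmptyPanelError(
            "all normal:normal pairs failed the contamination screen; "
            "use the hard_cutoff null model instead"
        )
    return NullPanel(kept)


def region_specific_test(
    segment: Segment,
    panel: NullPanel,
    percentile: float = DEFAULT_NULL_PERCENTILE,
    pooled: bool = False,
) -> str:
    """Compare a segment mean to the same region's panel distribution.

    The null statistic is the per-pair mean abs ΔVAF over the segment's span
    (one value per pair with overlapping sites); ``pooled=True`` ranks the
    segment against all panel site values pooled instead.  Significant at or
    above the requested empirical percentile (linear interpolation between
    order statistics).
    """
    if not segment.eligible:
        segment.significant = None
        segment.null_model = "region_specific"
        return VERDICT_INELIGIBLE
    if pooled:
        null_values = panel.pooled_region_values(segment.chrom, segment.start, segment.end)
    else:
        null_values = panel.region_means(segment.chrom, segment.start, segment.end)
    segment.null_model = "region_specific"
    if null_values.size == 0:
        segment.significant = None
        return VERDICT_NO_NULL_COVERAGE
    threshold = float(np.percentile(null_values, percentile))
    segment.significant = bool(segment.mean_abs_dvaf >= threshold)
    return VERDICT_SIGNIFICANT if segment.significant else VERDICT_NOT_SIGNIFICANT


def fold_change_test(
    external_segment: ExternalSegment,
    low: float = DEFAULT_FC_LOW,
    high: float = DEFAULT_FC_HIGH,
) -> bool:
    """Significant iff fold change < low or > high (both strict)."""
    fc = external_segment.fold_change
    if fc <= 0:
        raise ValueError("fold_change must be > 0")
    return fc < low or fc > high
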