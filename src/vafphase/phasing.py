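"""Assign variants to homologs by the sign of ΔVAF; merge phase sources.

Within a significant SCNA segment, every heterozygous variant with a
significant Fisher test is assigned a haplotype by the direction of its VAF
shift: hap 1 for the homolog over-represented in the tumor (ΔVAF > 0), hap 0
for the under-represented one.  Each significant segment yields one phase
block; labels are meaningful only within a block, up to a global flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import delta as _delta
from .cbs import (
    CBSParams,
    DEFAULT_MIN_LENGTH_BP,
    Segment,
    segment_chromosome,
)
from .model import ExternalPhaseCall, ExternalSegment, SiteKey, VariantSite, chrom_sort_key
from .significance import (
    DEFAULT_FC_HIGH,
    DEFAULT_FC_LOW,
    DEFAULT_HARD_CUTOFF,
    DEFAULT_NULL_PERCENTILE,
    NullPanel,
    VERDICT_NO_NULL_COVERAGE,
    fold_change_test,
    hard_cutoff_test,
    region_specific_test,
)

logger = logging.getLogger("vafphase")


@dataclass
class PhaseParams:
    """Operating point of the phasing pipeline (defaults as documented)."""

    fisher_alpha: float = _delta.DEFAULT_FISHER_ALPHA
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP
    cbs_n_permutations: int = 1000
    cbs_alpha: float = 0.01
    cbs_min_points: int = 2
    seed: int = 17
    null_model: str = "hard_cutoff"  # hard_cutoff | region_specific | fold_change
    hard_cutoff: float = DEFAULT_HARD_CUTOFF
    null_percentile: float = DEFAULT_NULL_PERCENTILE
    fc_low: float = DEFAULT_FC_LOW
    fc_high: float = DEFAULT_FC_HIGH
    panel_pooled: bool = False
    region_fallback: bool = True  # fall back to hard cutoff on no null coverage

    def cbs_params(self) -> CBSParams:
        return CBSParams(
            n_permutations=self.cbs_n_permutations,
            alpha_split=self.cbs_alpha,
            min_seg_points=self.cbs_min_points,
            seed=self.seed,
        )


@dataclass
class PhaseBlock:
    """A set of variants phased relative to one another."""

    block_id: str
    chrom: str
    source: str  # VAF, HAPCUT2, PHASER, MERGED, ...
    members: list[tuple[SiteKey, int]]  # (site key, hap in {0, 1})
    segment: Optional[Segment] = None

    def to_calls(self) -> list[ExternalPhaseCall]:
        return [
            ExternalPhaseCall(
                chrom=k[0], pos=k[1], ref=k[2], alt=k[3],
                source=self.source, block_id=self.block_id, hap=h,
            )
            for k, h in self.members
        ]


def assign_phase(
    segment: Segment,
    dvaf_results: Sequence[_delta.DeltaVAFResult],
) -> Optional[PhaseBlock]:
    """Phase a significant segment's members by sign of ΔVAF.

    ``dvaf_results`` is indexed by the same global site indices stored in
    ``segment.member_indices``.  Eligible members are heterozygous, Fisher
    significant and have ΔVAF != 0; a block is emitted only with >= 2
    eligible members.
    """
    members: list[tuple[SiteKey, int]] = []
    for idx in segment.member_indices:
        r = dvaf_results[int(idx)]
        if not r.site.is_het or not r.significant or r.dvaf == 0:
            continue
        members.append((r.site.key, 1 if r.dvaf > 0 else 0))
    if len(members) < 2:
        return None
    return PhaseBlock(
        block_id=f"VAF:{segment.segment_id}",
        chrom=segment.chrom,
        source="VAF",
        members=members,
        segment=segment,
    )


@dataclass
class PhaseResult:
    blocks: list[PhaseBlock]
    segments: list[Segment]
    dvaf_results: list[_delta.DeltaVAFResult]
    audit: pd.DataFrame

    @property
    def n_phased(self) -> int:
        return sum(len(b.members) for b in self.blocks)

    def calls(self) -> list[ExternalPhaseCall]:
        return [c for b in self.blocks for c in b.to_calls()]


def _external_to_segments(
    external_segments: Sequence[ExternalSegment],
    chroms: np.ndarray,
    positions: np.ndarray,
    abs_dvaf: np.ndarray,
    low: float,
    high: float,
) -> list[Segment]:
    """Turn external copy-ratio records into member-bearing segments with a
    fold-change significance verdict."""
    out: list[Segment] = []
    for ext in external_segments:
        mask = (chroms == ext.chrom) & (positions >= ext.start) & (positions <= ext.end)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        seg = Segment(
            chrom=ext.chrom,
            start=ext.start,
            end=ext.end,
            member_indices=idx,
            n_variants=int(idx.size),
            mean_abs_dvaf=float(abs_dvaf[idx].mean()),
            size_bp=ext.end - ext.start + 1,
            eligible=idx.size > 1,
        )
        seg.null_model = "fold_change"
        seg.significant = fold_change_test(ext, low, high) if seg.eligible else None
        out.append(seg)
    return out


def phase_sample(
    sites: Sequence[VariantSite],
    params: Optional[PhaseParams] = None,
    panel: Optional[NullPanel] = None,
    external_segments: Optional[Sequence[ExternalSegment]] = None,
) -> PhaseResult:
    """Run the full pipeline on one sample's sites.

    Steps: per-site ΔVAF + Fisher test; gap smoothing and CBS on the
    heterozygous sites' abs ΔVAF per chromosome; SCNA significance under the
    configured null model; haplotype assignment by sign of ΔVAF.  The audit
    table records, for every input site, its segment, verdicts and the
    reason it was or was not phased.
    """
    params = params or PhaseParams()
    keys = [s.key for s in sites]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (chrom, pos, ref, alt) keys in input sites")

    results = _delta.compute_delta_vafs(sites, params.fisher_alpha)
    chroms = np.array([s.chrom for s in sites], dtype=object)
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    absd = np.array([r.abs_dvaf for r in results], dtype=float)
    het = np.array([s.is_het for s in sites], dtype=bool)

    segments: list[Segment] = []
    if params.null_model == "fold_change":
        if external_segments is None:
            raise ValueError("null_model 'fold_change' requires external segments")
        het_idx = np.flatnonzero(het)
        segments = _external_to_segments(
            external_segments, chroms, positions, absd, params.fc_low, params.fc_high
        )
        # restrict members to heterozygous sites
        for seg in segments:
            seg.member_indices = np.intersect1d(seg.member_indices, het_idx)
            seg.n_variants = int(seg.member_indices.size)
            seg.eligible = seg.n_variants > 1
    elif params.null_model in ("hard_cutoff", "region_specific"):
        if params.null_model == "region_specific" and panel is None:
            raise ValueError("null_model 'region_specific' requires a null panel")
        rng = np.random.default_rng(params.seed)
        for chrom in sorted(set(chroms[het]), key=chrom_sort_key):
            mask = het & (chroms == chrom)
            idx = np.flatnonzero(mask)
            order = np.argsort(positions[idx], kind="stable")
            idx = idx[order]
            segs = segment_chromosome(
                str(chrom),
                positions[idx],
                absd[idx],
                idx,
                min_length=params.min_length_bp,
                params=params.cbs_params(),
                rng=rng,
            )
            segments.extend(segs)
        for seg in segments:
            if params.null_model == "hard_cutoff":
                hard_cutoff_test(seg, params.hard_cutoff)
            else:
                verdict = region_specific_test(
                    seg, panel, params.null_percentile, pooled=params.panel_pooled
                )
                if verdict == VERDICT_NO_NULL_COVERAGE and params.region_fallback:
                    logger.info(
                        "phase_sample: no null coverage for %s; falling back to "
                        "hard cutoff", seg.segment_id,
                    )
                    hard_cutoff_test(seg, params.hard_cutoff)
    else:
        raise ValueError(f"unknown null_model {params.null_model!r}")

    blocks: list[PhaseBlock] = []
    site_status = ["no_significant_segment"] * len(sites)
    site_hap: list[Optional[int]] = [None] * len(sites)
    site_segment: list[Optional[str]] = [None] * len(sites)
    for i in np.flatnonzero(~het):
        site_status[int(i)] = "not_heterozygous"

    for seg in segments:
        for idx in seg.member_indices:
            site_segment[int(idx)] = seg.segment_id
        if seg.significant is None:
            status = "ineligible_segment" if not seg.eligible else "no_null_coverage"
            for idx in seg.member_indices:
                site_status[int(idx)] = status
            continue
        if not seg.significant:
            for idx in seg.member_indices:
                site_status[int(idx)] = "segment_not_significant"
            continue
        block = assign_phase(seg, results)
        phased_keys = dict(block.members) if block else {}
        for idx in seg.member_indices:
            r = results[int(idx)]
            if not r.site.is_het:
                continue
            if not r.significant:
                site_status[int(idx)] = "fisher_not_significant"
            elif r.dvaf == 0:
                site_status[int(idx)] = "zero_dvaf"
            elif r.site.key in phased_keys:
                site_status[int(idx)] = "phased"
                site_hap[int(idx)] = phased_keys[r.site.key]
            else:
                site_status[int(idx)] = "singleton_block"
        if block:
            blocks.append(block)

    audit = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "is_het": het,
            "vaf_normal": [r.vaf_normal for r in results],
            "vaf_tumor": [r.vaf_tumor for r in results],
            "dvaf": [r.dvaf for r in results],
            "abs_dvaf": absd,
            "p_value": [r.p_value for r in results],
            "fisher_significant": [r.significant for r in results],
            "segment": site_segment,
            "hap": site_hap,
            "status": site_status,
        }
    )
    logger.info("phase_sample: phased %d of %d sites in %d block(s)",
                sum(s == "phased" for s in site_status), len(sites), len(blocks))
    return PhaseResult(blocks=blocks, segments=segments, dvaf_results=results, audit=audit)


# ---------------------------------------------------------------------------
# merging phase sources
# ---------------------------------------------------------------------------

@dataclass
class MergedPhase:
    calls: list[ExternalPhaseCall]
    provenance: dict[SiteKey, str] = field(default_factory=dict)


def _index_calls(calls: Sequence[ExternalPhaseCall], source: str) -> dict[SiteKey, ExternalPhaseCall]:
    out: dict[SiteKey, ExternalPhaseCall] = {}
    for c in calls:
        prev = out.get(c.key)
        if prev is not None and (prev.hap != c.hap or prev.block_id != c.block_id):
            raise ValueError(
                f"conflicting duplicate {source} calls for site "
                f"{c.chrom}:{c.pos} {c.ref}>{c.alt}"
            )
        out[c.key] = c
    return out


def merge_phase_sources(
    vaf_calls: Sequence[ExternalPhaseCall],
    hapcut2_calls: Sequence[ExternalPhaseCall],
    phaser_calls: Sequence[ExternalPhaseCall],
) -> MergedPhase:
    """Consolidate phase calls with priority VAF > read-backed.

    Sites phased by VAF keep the VAF call.  Sites phased by exactly one
    read-backed source keep that call.  Sites phased by both HapCUT2 and
    phASER are kept (as the HapCUT2 call) only when the two sources agree on
    the site's orientation within their common block, judged after anchoring
    on the first shared variant; with fewer than two shared variants the
    orientation cannot be compared and the call is kept.
    """
    vaf = _index_calls(vaf_calls, "VAF")
    hc = _index_calls(hapcut2_calls, "HAPCUT2")
    ph = _index_calls(phaser_calls, "PHASER")

    hc_blocks: dict[str, list[ExternalPhaseCall]] = {}
    for c in hc.values():
        hc_blocks.setdefault(c.block_id, []).append(c)
    ph_by_key = ph

    merged: list[ExternalPhaseCall] = []
    provenance: dict[SiteKey, str] = {}

    for key, call in vaf.items():
        merged.append(call)
        provenance[key] = call.source

    for key, call in hc.items():
        if key in provenance:
            continue
        other = ph_by_key.get(key)
        if other is None:
            merged.append(call)
            provenance[key] = call.source
            continue
        shared = [
            c.key for c in hc_blocks[call.block_id]
            if c.key in ph_by_key and ph_by_key[c.key].block_id == other.block_id
        ]
        if len(shared) < 2:
            merged.append(call)
            provenance[key] = call.source
            continue
        anchor = min(shared)
        flip = hc[anchor].hap != ph_by_key[anchor].hap
        expected = ph_by_key[key].hap ^ int(flip)
        if call.hap == expected:
            merged.append(call)
            provenance[key] = call.source
        else:
            logger.info(
                "merge_phase_sources: dropping %s:%d (HapCUT2/phASER orientation "
                "disagreement)", key[0], key[1],
            )

    for key, call in ph.items():
        if key not in provenance and key not in hc:
            merged.append(call)
            provenance[key] = call.source

    return MergedPhase(calls=merged, provenance=provenance)
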