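"""Compare two phasings: overall and pairwise discordance.

Haplotype labels are arbitrary per block, so comparisons are made within
*common blocks* (the >= 2-site intersections of one block from each method)
after aligning orientations: anchoring on the first shared variant makes
every metric invariant to global flips of either method's labels.

Overall discordance = 1 − concordant/common over all common blocks.
Pairwise discordance classifies every unordered variant pair within a common
block as discordant when the two methods disagree about whether the pair is
in cis (same hap) or trans (opposite haps), and bins pairs by genomic
distance and minimum population allele frequency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cbs import Segment
from .model import ExternalPhaseCall, SiteKey

DEFAULT_DISTANCE_EDGES = [10.0 ** e for e in range(2, 9)]  # 1e2 .. 1e8 bp
DEFAULT_AF_EDGES = [0.001, 0.01, 0.05]


@dataclass
class CommonBlock:
    """Shared-site intersection of one block from each of two methods."""

    block_a: str
    block_b: str
    keys: list[SiteKey]  # sorted by genomic position
    haps_a: np.ndarray
    haps_b: np.ndarray

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class PhasePair:
    """One unordered pair of commonly phased variants with its features."""

    key1: SiteKey
    key2: SiteKey
    orientation_a: str  # "cis" | "trans"
    orientation_b: str
    discordant: bool
    min_read_depth: Optional[int] = None
    segment_size_bp: Optional[int] = None
    segment_abs_dvaf: Optional[float] = None
    delta_dvaf: Optional[float] = None
    pair_distance_bp: Optional[int] = None
    delta_allele_freq: Optional[float] = None
    min_allele_freq: Optional[float] = None


@dataclass
class PairContext:
    """Per-site context used to populate phase-pair features.

    ``depths`` maps a site to its read depth (min of normal and tumor
    depth); ``segments`` to its VAF-CBS segment; ``dvaf`` to its ΔVAF;
    ``allele_freq`` to its population allele frequency.
    """

    depths: Mapping[SiteKey, int]
    segments: Mapping[SiteKey, Segment]
    dvaf: Mapping[SiteKey, float]
    allele_freq: Mapping[SiteKey, float]


def _group_blocks(calls: Sequence[ExternalPhaseCall]) -> dict[str, dict[SiteKey, int]]:
    blocks: dict[str, dict[SiteKey, int]] = {}
    for c in calls:
        blocks.setdefault(c.block_id, {})[c.key] = c.hap
    return blocks


def find_common_blocks(
    calls_a: Sequence[ExternalPhaseCall],
    calls_b: Sequence[ExternalPhaseCall],
) -> list[CommonBlock]:
    """All block pairs sharing >= 2 phased sites, as shared-site intersections."""
    blocks_a = _group_blocks(calls_a)
    blocks_b = _group_blocks(calls_b)
    out: list[CommonBlock] = []
    for id_a in sorted(blocks_a):
        a = blocks_a[id_a]
        for id_b in sorted(blocks_b):
            b = blocks_b[id_b]
            shared = sorted(set(a) & set(b), key=lambda k: (k[0], k[1], k[2], k[3]))
            if len(shared) < 2:
                continue
            out.append(
                CommonBlock(
                    block_a=id_a,
                    block_b=id_b,
                    keys=shared,
                    haps_a=np.array([a[k] for k in shared], dtype=int),
                    haps_b=np.array([b[k] for k in shared], dtype=int),
                )
            )
    return out


def overall_discordance(common_blocks: Sequence[CommonBlock]) -> float:
    """1 − concordant/common, orientations anchored on the first shared variant."""
    n_common = n_concordant = 0
    for blk in common_blocks:
        flip = int(blk.haps_a[0] != blk.haps_b[0])
        n_common += len(blk)
        n_concordant += int((blk.haps_a == (blk.haps_b ^ flip)).sum())
    if n_common == 0:
        raise ValueError("no commonly phased variants; discordance undefined")
    return 1.0 - n_concordant / n_common


def _distance_label(dist: int, edges: Sequence[float]) -> str:
    for e in edges:
        if dist < e:
            return f"<{e:g}"
    return f">={edges[-1]:g}"


def _af_label(af: Optional[float], edges: Sequence[float]) -> str:
    if af is None:
        return "unknown"
    if af == 0:
        return "singleton"
    for e in edges:
        if af < e:
            return f"<{e:g}"
    return f">={edges[-1]:g}"


def pairwise_discordance(
    common_blocks: Sequence[CommonBlock],
    distance_bins: Sequence[float] = DEFAULT_DISTANCE_EDGES,
    af_bins: Sequence[float] = DEFAULT_AF_EDGES,
    allele_freq: Optional[Mapping[SiteKey, float]] = None,
) -> pd.DataFrame:
    """Classify every unordered in-block pair; tabulate by distance × AF bin.

    A pair is discordant when the two methods disagree on its relative
    orientation (cis vs trans).  Pairs are binned by base-pair distance and
    by the minimum allele frequency of the pair.
    """
    if len(distance_bins) == 0 or len(af_bins) == 0:
        raise ValueError("distance and AF bin edges must be non-empty")
    rows: list[tuple[str, str, bool]] = []
    for blk in common_blocks:
        for i, j in itertools.combinations(range(len(blk)), 2):
            same_a = blk.haps_a[i] == blk.haps_a[j]
            same_b = blk.haps_b[i] == blk.haps_b[j]
            discordant = same_a != same_b
            dist = abs(blk.keys[j][1] - blk.keys[i][1])
            if allele_freq is not None:
                afs = [allele_freq.get(blk.keys[i]), allele_freq.get(blk.keys[j])]
                af = None if any(a is None for a in afs) else min(afs)
            else:
                af = None
            rows.append((_distance_label(dist, distance_bins), _af_label(af, af_bins), discordant))
    df = pd.DataFrame(rows, columns=["distance_bin", "af_bin", "discordant"])
    if df.empty:
        return pd.DataFrame(
            columns=["distance_bin", "af_bin", "n_pairs", "n_discordant", "discordance"]
        )
    grouped = (
        df.groupby(["distance_bin", "af_bin"], as_index=False)
        .agg(n_pairs=("discordant", "size"), n_discordant=("discordant", "sum"))
    )
    grouped["discordance"] = grouped["n_discordant"] / grouped["n_pairs"]
    return grouped


def pair_features(
    key1: SiteKey,
    key2: SiteKey,
    orientation_a: str,
    orientation_b: str,
    context: PairContext,
) -> PhasePair:
    """Populate the per-pair features used to model phase errors.

    Features: minimum read depth of the pair, size and mean abs ΔVAF of the
    VAF-CBS segment, ΔΔVAF (|difference in ΔVAF|), pair distance in bp, and
    Δ / minimum allele frequency.  Missing allele frequencies are recorded
    as unavailable (None).
    """
    if key1[0] != key2[0]:
        raise ValueError(f"pair spans chromosomes {key1[0]} and {key2[0]}")
    depths = [context.depths.get(key1), context.depths.get(key2)]
    seg = context.segments.get(key1) or context.segments.get(key2)
    d1, d2 = context.dvaf.get(key1), context.dvaf.get(key2)
    af1, af2 = context.allele_freq.get(key1), context.allele_freq.get(key2)
    return PhasePair(
        key1=key1,
        key2=key2,
        orientation_a=orientation_a,
        orientation_b=orientation_b,
        discordant=orientation_a != orientation_b,
        min_read_depth=None if any(d is None for d in depths) else min(depths),
        segment_size_bp=None if seg is None else seg.size_bp,
        segment_abs_dvaf=None if seg is None else seg.mean_abs_dvaf,
        delta_dvaf=None if d1 is None or d2 is None else abs(d1 - d2),
        pair_distance_bp=abs(key2[1] - key1[1]),
        delta_allele_freq=None if af1 is None or af2 is None else abs(af1 - af2),
        min_allele_freq=None if af1 is None or af2 is None else min(af1, af2),
    )
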