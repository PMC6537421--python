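"""Shared domain types for VAF phasing.

The central object is :class:`VariantSite`: one heterozygous germline variant
with paired reference/alternate read counts from a normal and a tumor sample.
Everything downstream (ΔVAF, segmentation, phase blocks) is derived from lists
of these sites.

Haplotype labels are binary and meaningful only *within* a phase block, up to
a global flip: by convention hap 1 marks the homolog over-represented in the
tumor (positive ΔVAF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: (chrom, pos, ref, alt) — the unique key of a variant within a sample.
SiteKey = tuple[str, int, str, str]


class VafPhaseError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VafPhaseError):
    """A malformed input file (missing column, bad field, absent FORMAT tag)."""


@dataclass(frozen=True)
class VariantSite:
    """A germline variant with paired normal/tumor allele counts.

    Counts are raw read counts supporting the reference (``*_ref``) and the
    alternate (``*_alt``) allele in the normal (``n_``) and tumor (``t_``)
    sample.  Sites entering analysis must have depth >= 1 in both samples;
    readers drop tumor-depth-zero sites.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    n_ref: int
    n_alt: int
    t_ref: int
    t_alt: int
    is_het: bool = True
    allele_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("n_ref", "n_alt", "t_ref", "t_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def normal_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def tumor_depth(self) -> int:
        return self.t_ref + self.t_alt


@dataclass(frozen=True)
class ExternalSegment:
    """An externally segmented copy-ratio record (SEG-like).

    ``fold_change`` is the estimated total copy ratio relative to diploid;
    1.0 means two copies, 1.1 corresponds to a single-chromosome gain in 20%
    of tumor cells.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    fold_change: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass(frozen=True)
class ExternalPhaseCall:
    """One phased-site record from any phasing source.

    ``hap`` is 0 or 1 and is arbitrary but consistent within ``block_id``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    source: str  # VAF, HAPCUT2, PHASER, TENX, SHAPEIT, TRUTH, MERGED
    block_id: str
    hap: int

    def __post_init__(self) -> None:
        if self.hap not in (0, 1):
            raise ValueError(f"hap must be 0 or 1, got {self.hap}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort chromosomes numerically where possible (1..22 < X < Y < others)."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (special[c.upper()], "")
    return (99, c)
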