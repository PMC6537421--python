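"""Synthetic paired tumor:normal allele-count data with known truth.

The tumor is modeled as a mixture of tumor cells (fraction ``purity``) and
normal cells.  Within an SCNA event the two homologs carry ``copies_a`` and
``copies_b`` copies in tumor cells (normal cells stay 1:1), so the expected
tumor VAF of a heterozygous variant whose alternate allele lies on the
homolog with ``c`` copies (partner at ``c'``) is

    E[VAF] = (purity·c + (1−purity)) / (purity·(c + c') + (1−purity)·2)

Read counts are binomial draws at Poisson (optionally negative-binomial)
depths: the minimal noise model for read sampling error.  All randomness
flows through one seeded generator, so outputs are bit-reproducible.

The default configuration encodes the pipeline's reference study
conditions: purity 0.6, mean depth 100, 200 sites on each of three 60 Mb
chromosomes, and one clearly mono-allelic SCNA per chromosome —
copy-neutral LOH (2,0), single-copy deletion (1,0) and focal amplification
(6,1), i.e. expected |ΔVAF| of 0.30 / 0.21 / 0.30.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import VariantSite
from .phasing import PhaseBlock


@dataclass(frozen=True)
class ScnaEvent:
    """One somatic copy-number event: per-homolog copies over an interval."""

    chrom: str
    start: int
    end: int
    copies_a: int  # tumor-cell copies of homolog A (hap 0)
    copies_b: int  # tumor-cell copies of homolog B (hap 1)

    def __post_init__(self) -> None:
        if self.copies_a < 0 or self.copies_b < 0:
            raise ValueError("copy numbers must be non-negative integers")
        if self.start > self.end:
            raise ValueError("event start > end")


def _default_events() -> list[ScnaEvent]:
    return [
        ScnaEvent("1", 10_000_000, 25_000_000, 2, 0),  # copy-neutral LOH
        ScnaEvent("2", 10_000_000, 25_000_000, 1, 0),  # single-copy deletion
        ScnaEvent("3", 10_000_000, 25_000_000, 6, 1),  # focal amplification
    ]


def _default_chroms() -> dict[str, int]:
    return {"1": 60_000_000, "2": 60_000_000, "3": 60_000_000}


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    n_sites: int = 200  # heterozygous sites per chromosome
    events: list[ScnaEvent] = field(default_factory=_default_events)
    purity: float = 0.6
    normal_depth: float = 100.0
    tumor_depth: float = 100.0
    depth_model: str = "poisson"  # poisson | nbinom
    nb_dispersion: float = 3.0  # nbinom shape; larger = closer to Poisson
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must be in [0, 1]")
        if self.normal_depth <= 0 or self.tumor_depth <= 0:
            raise ValueError("mean depths must be > 0")
        if self.depth_model not in ("poisson", "nbinom"):
            raise ValueError(f"unknown depth model {self.depth_model!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class SimTruth:
    """Ground truth: per-site haplotype, expected tumor VAF, region."""

    sites: pd.DataFrame  # chrom,pos,ref,alt,true_hap,expected_vaf,region
    events: list[ScnaEvent]

    def hap_by_key(self) -> dict[tuple, int]:
        return {
            (r.chrom, r.pos, r.ref, r.alt): int(r.true_hap)
            for r in self.sites.itertuples(index=False)
        }

    def region_by_key(self) -> dict[tuple, Optional[str]]:
        return {
            (r.chrom, r.pos, r.ref, r.alt): (None if pd.isna(r.region) else r.region)
            for r in self.sites.itertuples(index=False)
        }


def expected_tumor_vaf(copies_carrier: int, copies_other: int, purity: float) -> float:
    """Expected tumor VAF for a het site whose alt lies on the carrier homolog.

    The tumor sample is a mixture: tumor cells contribute ``copies_carrier``
    alternate-bearing and ``copies_other`` reference-bearing chromosomes,
    normal cells one of each.
    """
    if copies_carrier < 0 or copies_other < 0:
        raise ValueError("copy numbers must be non-negative")
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    num = purity * copies_carrier + (1 - purity) * 1.0
    den = purity * (copies_carrier + copies_other) + (1 - purity) * 2.0
    if den == 0:
        raise ValueError("zero expected depth: purity 1 with both homologs at 0 copies")
    return num / den


def expected_fold_change(copies_a: int, copies_b: int, purity: float) -> float:
    """Total copy ratio of the mixed tumor sample relative to diploid."""
    return (purity * (copies_a + copies_b) + (1 - purity) * 2.0) / 2.0


def _draw_depths(rng: np.random.Generator, mean: float, n: int, config: SimConfig) -> np.ndarray:
    if config.depth_model == "poisson":
        d = rng.poisson(mean, size=n)
    else:
        shape = config.nb_dispersion
        d = rng.negative_binomial(shape, shape / (shape + mean), size=n)
    return np.maximum(d, 1)


def simulate_pair(config: Optional[SimConfig] = None) -> tuple[list[VariantSite], SimTruth]:
    """Draw one paired tumor:normal sample with known haplotypes."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    sites: list[VariantSite] = []
    rows: list[dict] = []
    for chrom in config.chrom_lengths:
        length = config.chrom_lengths[chrom]
        pos = np.sort(
            rng.choice(np.arange(1, length + 1), size=config.n_sites, replace=False)
        )
        haps = rng.integers(0, 2, size=config.n_sites)
        events = [e for e in config.events if e.chrom == chrom]
        for p, h in zip(pos, haps):
            region = None
            copies = (1, 1)
            for e in events:
                if e.start <= p <= e.end:
                    region = f"{e.chrom}:{e.start}-{e.end}"
                    copies = (e.copies_a, e.copies_b)
                    break
            carrier = copies[h]
            other = copies[1 - h]
            ev = expected_tumor_vaf(carrier, other, config.purity)
            dn = int(_draw_depths(rng, config.normal_depth, 1, config)[0])
            dt = int(_draw_depths(rng, config.tumor_depth, 1, config)[0])
            n_alt = int(rng.binomial(dn, 0.5))
            t_alt = int(rng.binomial(dt, ev))
            sites.append(
                VariantSite(
                    chrom=chrom, pos=int(p), ref="A", alt="G",
                    n_ref=dn - n_alt, n_alt=n_alt, t_ref=dt - t_alt, t_alt=t_alt,
                )
            )
            rows.append(
                dict(chrom=chrom, pos=int(p), ref="A", alt="G",
                     true_hap=int(h), expected_vaf=ev, region=region)
            )
    truth = SimTruth(sites=pd.DataFrame(rows), events=list(config.events))
    return sites, truth


@dataclass(frozen=True)
class Contamination:
    """A CNA-like shift injected into one null-panel pair (for screen tests)."""

    chrom: str
    start: int
    end: int
    vaf_shift: float  # expected |ΔVAF| inside the region


def simulate_null_panel(
    config: Optional[SimConfig] = None,
    n_pairs: int = 2,
    contaminate: Optional[dict[int, Contamination]] = None,
) -> list[list[VariantSite]]:
    """Draw normal:normal replicate pairs (no CNAs; both samples at VAF 0.5).

    ``contaminate`` maps pair indices to an injected shifted region, used to
    exercise the panel's contamination screen.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    contaminate = contaminate or {}
    panel: list[list[VariantSite]] = []
    for pair_idx in range(n_pairs):
        pair: list[VariantSite] = []
        for chrom, length in config.chrom_lengths.items():
            pos = np.sort(rng.choice(np.arange(1, length + 1), size=config.n_sites, replace=False))
            haps = rng.integers(0, 2, size=config.n_sites)
            d1 = _draw_depths(rng, config.normal_depth, config.n_sites, config)
            d2 = _draw_depths(rng, config.normal_depth, config.n_sites, config)
            for p, h, a, b in zip(pos, haps, d1, d2):
                p2 = 0.5
                cont = contaminate.get(pair_idx)
                if cont and cont.chrom == chrom and cont.start <= p <= cont.end:
                    p2 = 0.5 + cont.vaf_shift * (1 if h else -1)
                a1 = int(rng.binomial(a, 0.5))
                a2 = int(rng.binomial(b, p2))
                pair.append(
                    VariantSite(
                        chrom=chrom, pos=int(p), ref="A", alt="G",
                        n_ref=int(a) - a1, n_alt=a1, t_ref=int(b) - a2, t_alt=a2,
                    )
                )
        panel.append(pair)
    return panel


@dataclass
class PhaseAccuracy:
    """Variant-weighted accuracy of phase calls against simulation truth."""

    n_phased: int
    n_correct: int  # under the best global flip per block
    accuracy: float  # n_correct / n_phased (1.0 when nothing phased)
    frac_phased: float  # phased / all truth sites
    n_false_diploid: int  # phased sites lying in truly diploid territory
    frac_false_diploid: float  # false-phased / diploid truth sites


def evaluate_phase_accuracy(truth: SimTruth, blocks: Sequence[PhaseBlock]) -> PhaseAccuracy:
    """Score blocks against truth, flip-invariantly per block."""
    true_hap = truth.hap_by_key()
    region = truth.region_by_key()
    n_phased = n_correct = n_false = 0
    for block in blocks:
        member_truth = [(h, true_hap.get(k)) for k, h in block.members]
        known = [(h, t) for h, t in member_truth if t is not None]
        matches = sum(1 for h, t in known if h == t)
        n_correct += max(matches, len(known) - matches)
        n_phased += len(known)
        n_false += sum(1 for k, _ in block.members if region.get(k, None) is None)
    n_sites = len(truth.sites)
    n_diploid = sum(1 for v in region.values() if v is None)
    return PhaseAccuracy(
        n_phased=n_phased,
        n_correct=n_correct,
        accuracy=(n_correct / n_phased) if n_phased else 1.0,
        frac_phased=(n_phased / n_sites) if n_sites else 0.0,
        n_false_diploid=n_false,
        frac_false_diploid=(n_false / n_diploid) if n_diploid else 0.0,
    )
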