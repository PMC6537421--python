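"""Phase-aware gene-level classification of damaging variant combinations.

A gene variant set collects one individual's nonsynonymous variants in one
gene together with their haplotype assignments.  Classification follows
standard clinical-genetics logic: a gene with damaging variants on *both*
copies (trans configuration, compound heterozygosity — a homozygous damaging
variant alone also alters both copies) is distinguished from a gene with
multiple damaging variants on *one* copy (cis), from mono-allelic hits, and
from genes whose damaging variants cannot be phase-resolved.

Damaging calls: CADD score >= 15; ClinVar-pathogenic when at least half the
contributing submissions say Pathogenic / Likely pathogenic; loss-of-function
variants count only when rare (AF < 0.05) in every supplied ancestry group.

Variant *sets* on one gene copy can additionally be classified from an
external conservation-model score of the joint haplotype: with
range = max − min of the individual variant scores, a set score
<= min − 1.5·range is compensatory (jointly less damaging than the parts)
and >= max + 1.5·range is non-compensatory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .model import FormatError, SiteKey

logger = logging.getLogger("vafphase")

DEFAULT_CADD_THRESHOLD = 15.0
DEFAULT_LOF_AF_MAX = 0.05
SET_SCORE_FACTOR = 1.5

PATHOGENIC_LABELS = {"pathogenic", "likely pathogenic", "likely_pathogenic"}

EVENT_TRANS = "trans"
EVENT_CIS = "cis"
EVENT_MONO = "mono"
EVENT_UNRESOLVED = "unresolved"
EVENT_NONE = "none"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with annotations and (possibly missing) phase."""

    key: SiteKey
    gene: str
    cadd: Optional[float] = None
    clinvar_labels: tuple[str, ...] = ()
    lof: bool = False
    allele_freqs: tuple[float, ...] = ()  # per ancestry group
    hap: Optional[int] = None  # 0 / 1 / None (unphased)
    homozygous: bool = False


@dataclass
class GeneVariantSet:
    """One individual's variants in one gene, plus optional set scores."""

    gene: str
    variants: list[AnnotatedVariant]
    set_score: Optional[float] = None
    individual_scores: Optional[list[float]] = None


def is_damaging_cadd(variant: AnnotatedVariant, threshold: float = DEFAULT_CADD_THRESHOLD) -> bool:
    """CADD >= threshold (inclusive); missing score is not damaging."""
    if variant.cadd is None:
        logger.debug("no CADD score for %s; treated as not damaging", variant.key)
        return False
    return variant.cadd >= threshold


def is_clinvar_pathogenic(submission_labels: Sequence[str]) -> bool:
    """At least half the contributing sources call it (Likely) Pathogenic."""
    labels = [str(s).strip().lower() for s in submission_labels if str(s).strip()]
    if not labels:
        return False
    n_path = sum(1 for s in labels if s in PATHOGENIC_LABELS)
    return n_path / len(labels) >= 0.5


def is_qualifying_lof(variant: AnnotatedVariant, af_max: float = DEFAULT_LOF_AF_MAX) -> bool:
    """LOF variants count only when AF < af_max in all ancestry groups."""
    if not variant.lof:
        return False
    return all(af < af_max for af in variant.allele_freqs)


def detect_gene_events(
    gene_set: GeneVariantSet, cadd_threshold: float = DEFAULT_CADD_THRESHOLD
) -> str:
    """Classify the damaging-variant configuration of one gene.

    trans — damaging variants occupy both haplotypes (a homozygous damaging
    variant alone qualifies); cis — >= 2 phased damaging variants share one
    haplotype with none phased to the other; mono — exactly one damaging
    variant; unresolved — multiple damaging variants whose phase cannot
    settle trans vs cis; none — no damaging variants.
    """
    damaging = [v for v in gene_set.variants if is_damaging_cadd(v, cadd_threshold)]
    if not damaging:
        return EVENT_NONE
    if any(v.homozygous for v in damaging):
        return EVENT_TRANS  # both copies altered by the homozygous variant
    phased = [v for v in damaging if v.hap in (0, 1)]
    haps = {v.hap for v in phased}
    if haps == {0, 1}:
        return EVENT_TRANS
    if len(damaging) == 1:
        return EVENT_MONO
    if len(phased) == len(damaging) and len(haps) == 1 and len(phased) >= 2:
        return EVENT_CIS
    return EVENT_UNRESOLVED


class SetScoreCall(NamedTuple):
    label: str  # compensatory | non_compensatory | neutral
    degenerate: bool  # all individual scores equal (range 0)


def classify_set_score(set_score: float, individual_scores: Sequence[float]) -> SetScoreCall:
    """Classify a joint haplotype score against its per-variant scores.

    With range = max − min of the individual scores: compensatory when
    set_score <= min − 1.5·range, non-compensatory when
    set_score >= max + 1.5·range, else neutral.  A zero range (all
    individual scores equal) is flagged degenerate: any set score strictly
    off the common value classifies.
    """
    scores = list(individual_scores)
    if len(scores) < 2:
        raise ValueError("set classification requires >= 2 variants")
    lo, hi = min(scores), max(scores)
    rng = hi - lo
    t_comp = lo - SET_SCORE_FACTOR * rng
    t_non = hi + SET_SCORE_FACTOR * rng
    if set_score <= t_comp:
        label = "compensatory"
    elif set_score >= t_non:
        label = "non_compensatory"
    else:
        label = "neutral"
    return SetScoreCall(label=label, degenerate=rng == 0)


@dataclass
class GeneSummary:
    """Per-gene evidence feeding the hierarchical grouping."""

    gene: str
    event: str  # trans/cis/mono/unresolved/none
    clinvar_lof: bool  # any ClinVar-pathogenic or qualifying LOF variant
    cadd_damaging: bool  # any CADD-damaging variant
    set_class: Optional[str] = None  # compensatory | non_compensatory | neutral


def summarize_gene(
    gene_set: GeneVariantSet,
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD,
    lof_af_max: float = DEFAULT_LOF_AF_MAX,
) -> GeneSummary:
    event = detect_gene_events(gene_set, cadd_threshold)
    clinvar_lof = any(
        is_clinvar_pathogenic(v.clinvar_labels) or is_qualifying_lof(v, lof_af_max)
        for v in gene_set.variants
    )
    cadd_damaging = any(is_damaging_cadd(v, cadd_threshold) for v in gene_set.variants)
    set_class = None
    if gene_set.set_score is not None and gene_set.individual_scores:
        if len(gene_set.individual_scores) >= 2:
            set_class = classify_set_score(
                gene_set.set_score, gene_set.individual_scores
            ).label
    return GeneSummary(
        gene=gene_set.gene,
        event=event,
        clinvar_lof=clinvar_lof,
        cadd_damaging=cadd_damaging,
        set_class=set_class,
    )


#: hierarchical mutually exclusive grouping schemes (first matching tier wins)
GROUP_SCHEMES = {
    "comphet": (
        ("Trans", lambda s: s.event == EVENT_TRANS),
        ("Cis", lambda s: s.event == EVENT_CIS),
        ("ClinVar/LOF", lambda s: s.clinvar_lof),
        ("CADD", lambda s: s.cadd_damaging),
    ),
    "hmmvar": (
        ("Non-Compensatory", lambda s: s.set_class == "non_compensatory"),
        ("Compensatory", lambda s: s.set_class == "compensatory"),
        ("ClinVar/LOF", lambda s: s.clinvar_lof),
        ("CADD", lambda s: s.cadd_damaging),
    ),
}


def assign_group(summaries: Sequence[GeneSummary], scheme: str = "comphet") -> str:
    """Assign an individual to one mutually exclusive group.

    The label is the highest-precedence tier matched by *any* gene in the
    supplied list; an individual with no qualifying variants is "none".
    """
    if scheme not in GROUP_SCHEMES:
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    for label, pred in GROUP_SCHEMES[scheme]:
        if any(pred(s) for s in summaries):
            return label
    return "none"


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[SiteKey, AnnotatedVariant]:
    """Read a per-variant annotation table.

    Required columns: chrom, pos, ref, alt, gene.  Optional: cadd,
    clinvar_labels (semicolon-joined), lof_flag (0/1), and any number of
    ``af_*`` columns (one per ancestry group) or a single ``af`` column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt", "gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table {path} is missing column(s): {', '.join(missing)}")
    af_cols = [c for c in df.columns if c == "af" or c.startswith("af_")]
    out: dict[SiteKey, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        key: SiteKey = (str(rec["chrom"]), int(rec["pos"]), str(rec["ref"]), str(rec["alt"]))
        labels: tuple[str, ...] = ()
        if "clinvar_labels" in rec and not pd.isna(rec["clinvar_labels"]):
            labels = tuple(s for s in str(rec["clinvar_labels"]).split(";") if s)
        cadd = None
        if "cadd" in rec and not pd.isna(rec["cadd"]):
            cadd = float(rec["cadd"])
        afs = tuple(float(rec[c]) for c in af_cols if not pd.isna(rec[c]))
        out[key] = AnnotatedVariant(
            key=key,
            gene=str(rec["gene"]),
            cadd=cadd,
            clinvar_labels=labels,
            lof=bool(int(rec["lof_flag"])) if "lof_flag" in rec and not pd.isna(rec["lof_flag"]) else False,
            allele_freqs=afs,
        )
    return out


def build_gene_sets(
    annotations: Mapping[SiteKey, AnnotatedVariant],
    haps: Mapping[SiteKey, int],
    homozygous: Optional[set[SiteKey]] = None,
    genes: Optional[Sequence[str]] = None,
) -> dict[str, GeneVariantSet]:
    """Group annotated variants by gene, attaching phase and zygosity."""
    import dataclasses

    homozygous = homozygous or set()
    by_gene: dict[str, GeneVariantSet] = {}
    for key, ann in annotations.items():
        if genes is not None and ann.gene not in genes:
            continue
        v = dataclasses.replace(
            ann, hap=haps.get(key), homozygous=key in homozygous
        )
        by_gene.setdefault(ann.gene, GeneVariantSet(gene=ann.gene, variants=[])).variants.append(v)
    return by_gene
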