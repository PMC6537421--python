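"""Readers and writers for the formats the tool touches.

Tabular formats (counts table, SEG-like segment table) go through pandas;
VCF input/output goes through pysam.  Coordinates are 1-based inclusive
everywhere, matching the VCF convention.

Phased genotypes are written with the standard phase-set convention: a phased
``GT`` (``0|1`` / ``1|0``) plus an integer ``PS`` tag shared by all members of
a block (the smallest member position).  ``hap`` is the first allele of the
phased genotype, so hap 0 round-trips as ``0|1`` and hap 1 as ``1|0``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    ExternalPhaseCall,
    ExternalSegment,
    FormatError,
    VariantSite,
    chrom_sort_key,
)

logger = logging.getLogger("vafphase")

COUNTS_COLUMNS = ["chrom", "pos", "ref", "alt", "n_ref", "n_alt", "t_ref", "t_alt"]


# ---------------------------------------------------------------------------
# counts table
# ---------------------------------------------------------------------------

def read_counts_table(path: str | Path) -> list[VariantSite]:
    """Read a tab-separated counts table into VariantSites.

    Required header columns: chrom, pos, ref, alt, n_ref, n_alt, t_ref,
    t_alt; optional ``af`` (population allele frequency) and ``is_het``.
    Lines starting with ``#`` are treated as comments.  Rows with tumor
    depth 0 are dropped (germline variants absent from the somatic data are
    not usable) and the exclusion count is logged.
    """
    path = Path(path)
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"counts table {path} is missing column(s): {', '.join(missing)}")

    sites: list[VariantSite] = []
    n_excluded = 0
    header_line = n_comment + 1
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = header_line + 1 + idx
        rec = dict(zip(df.columns, row))
        try:
            pos = int(rec["pos"])
            counts = {c: int(rec[c]) for c in ("n_ref", "n_alt", "t_ref", "t_alt")}
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{line_no}: non-integer count field ({exc})") from exc
        if counts["t_ref"] + counts["t_alt"] == 0:
            n_excluded += 1
            continue
        af = None
        if "af" in df.columns and not pd.isna(rec["af"]) and rec["af"] != "":
            af = float(rec["af"])
        is_het = True
        if "is_het" in df.columns and not pd.isna(rec["is_het"]):
            is_het = str(rec["is_het"]).lower() in ("1", "true", "t", "yes")
        sites.append(
            VariantSite(
                chrom=str(rec["chrom"]),
                pos=pos,
                ref=str(rec["ref"]),
                alt=str(rec["alt"]),
                is_het=is_het,
                allele_freq=af,
                **counts,
            )
        )
    if n_excluded:
        logger.info("read_counts_table: excluded %d site(s) with zero tumor depth", n_excluded)
    return sites


def write_counts_table(
    sites: Iterable[VariantSite],
    path: str | Path,
    provenance: Optional[Sequence[str]] = None,
) -> None:
    """Write VariantSites as a counts TSV (inverse of :func:`read_counts_table`)."""
    sites = list(sites)
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "n_ref": [s.n_ref for s in sites],
            "n_alt": [s.n_alt for s in sites],
            "t_ref": [s.t_ref for s in sites],
            "t_alt": [s.t_alt for s in sites],
            "is_het": [int(s.is_het) for s in sites],
            "af": [("" if s.allele_freq is None else repr(s.allele_freq)) for s in sites],
        }
    )
    with open(path, "w") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_paired_vcf(normal_vcf: str | Path, tumor_vcf: str | Path) -> list[VariantSite]:
    """Join heterozygous normal-VCF sites to tumor allelic depths.

    Both VCFs must carry a per-sample ``AD`` (allelic depth) FORMAT field.
    Only biallelic records are used; multiallelic records are skipped with a
    warning.  Sites absent from the tumor VCF, or with tumor depth 0, are
    dropped.
    """
    with pysam.VariantFile(str(tumor_vcf)) as tf:
        if "AD" not in tf.header.formats:
            raise FormatError(f"{tumor_vcf}: no AD FORMAT field in header")
        tumor_contigs = set(tf.header.contigs)
        tumor_ad: dict[tuple, tuple[int, int]] = {}
        for rec in tf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ad = rec.samples[0].get("AD")
            if ad is None:
                continue
            tumor_ad[(rec.chrom, rec.pos, rec.ref, rec.alts[0])] = (int(ad[0]), int(ad[1]))

    sites: list[VariantSite] = []
    n_multi = n_dropped = 0
    bad_contigs: set[str] = set()
    with pysam.VariantFile(str(normal_vcf)) as nf:
        if "AD" not in nf.header.formats:
            raise FormatError(f"{normal_vcf}: no AD FORMAT field in header")
        for rec in nf:
            if rec.alts is None:
                continue
            if len(rec.alts) != 1:
                n_multi += 1
                logger.warning(
                    "read_paired_vcf: skipping multiallelic site %s:%d", rec.chrom, rec.pos
                )
                continue
            gt = rec.samples[0].get("GT")
            if gt is None or set(gt) != {0, 1}:
                continue  # not a heterozygous 0/1 genotype
            if tumor_contigs and rec.chrom not in tumor_contigs:
                bad_contigs.add(rec.chrom)
                continue
            ad = rec.samples[0].get("AD")
            if ad is None:
                raise FormatError(f"{normal_vcf}: record {rec.chrom}:{rec.pos} has no AD")
            key = (rec.chrom, rec.pos, rec.ref, rec.alts[0])
            t = tumor_ad.get(key)
            if t is None or t[0] + t[1] == 0:
                n_dropped += 1
                continue
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    n_ref=int(ad[0]),
                    n_alt=int(ad[1]),
                    t_ref=t[0],
                    t_alt=t[1],
                    is_het=True,
                )
            )
    if bad_contigs:
        raise FormatError(
            "contig(s) present in normal VCF but absent from tumor VCF: "
            + ", ".join(sorted(bad_contigs))
        )
    if n_dropped:
        logger.info("read_paired_vcf: dropped %d site(s) with no tumor coverage", n_dropped)
    return sites


# ---------------------------------------------------------------------------
# phased VCF output / input
# ---------------------------------------------------------------------------

def write_phased_vcf(
    calls: Iterable[ExternalPhaseCall],
    template_vcf: str | Path,
    path: str | Path,
) -> None:
    """Write phased genotypes into a copy of ``template_vcf``.

    Sites with a call get a phased GT (hap 0 -> ``0|1``, hap 1 -> ``1|0``)
    and a PS tag equal to the smallest member position of their block;
    unphased sites are copied unchanged.
    """
    calls = list(calls)
    by_key = {c.key: c for c in calls}
    if len(by_key) != len(calls):
        raise ValueError("duplicate phase calls for the same site")
    block_ps: dict[str, int] = {}
    for c in calls:
        block_ps[c.block_id] = min(block_ps.get(c.block_id, c.pos), c.pos)

    with pysam.VariantFile(str(template_vcf)) as tmpl:
        header = tmpl.header.copy()
        if calls and "PS" not in header.formats:
            header.formats.add("PS", 1, "Integer", "Phase set identifier")
        seen: set = set()
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for rec in tmpl:
                rec.translate(header)
                alt = rec.alts[0] if rec.alts else None
                call = by_key.get((rec.chrom, rec.pos, rec.ref, alt))
                if call is not None:
                    seen.add(call.key)
                    sample = rec.samples[0]
                    sample["GT"] = (0, 1) if call.hap == 0 else (1, 0)
                    sample.phased = True
                    sample["PS"] = block_ps[call.block_id]
                out.write(rec)
    missing = set(by_key) - seen
    if missing:
        key = sorted(missing)[0]
        raise ValueError(
            f"phase call for site {key[0]}:{key[1]} {key[2]}>{key[3]} absent from template"
        )


def read_external_phase(path: str | Path, source: str = "EXTERNAL") -> list[ExternalPhaseCall]:
    """Read phased heterozygous genotypes (GT + PS) from a VCF."""
    out: list[ExternalPhaseCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or not sample.phased or set(gt) != {0, 1}:
                continue
            ps = sample.get("PS")
            if ps is None:
                continue
            out.append(
                ExternalPhaseCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    source=source,
                    block_id=f"{rec.chrom}:{ps}",
                    hap=int(gt[0]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# segment tables
# ---------------------------------------------------------------------------

def write_segments(
    segments: Iterable,
    path: str | Path,
    sample: str = "sample",
    provenance: Optional[Sequence[str]] = None,
) -> None:
    """Write segments as SEG-like TSV, sorted by (chrom, start).

    Columns: sample, chrom, start, end, n_variants, mean_abs_dvaf,
    significant, null_model.
    """
    rows = sorted(segments, key=lambda s: (chrom_sort_key(s.chrom), s.start))

    def fmt_sig(s) -> str:
        return "NA" if s.significant is None else str(bool(s.significant)).lower()

    with open(path, "w") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        fh.write(
            "sample\tchrom\tstart\tend\tn_variants\tmean_abs_dvaf\tsignificant\tnull_model\n"
        )
        for s in rows:
            fh.write(
                f"{sample}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_variants}\t"
                f"{s.mean_abs_dvaf:.6g}\t{fmt_sig(s)}\t{s.null_model or 'NA'}\n"
            )


def read_external_segments(path: str | Path) -> list[ExternalSegment]:
    """Read externally segmented copy-ratio records.

    Requires columns chrom, start, end, fold_change; other columns ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("chrom", "start", "end", "fold_change") if c not in df.columns]
    if missing:
        raise FormatError(f"segment table {path} is missing column(s): {', '.join(missing)}")
    return [
        ExternalSegment(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end), fold_change=float(r.fold_change)
        )
        for r in df.itertuples(index=False)
    ]
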