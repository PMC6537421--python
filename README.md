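# vafphase

Haplotype phasing of germline variants from paired tumor:normal sequencing
data, using somatic copy-number alterations (SCNAs) as the phasing signal.

## The idea

In a region where the tumor has gained or lost chromosomal material, one
homologous chromosome is physically more abundant than its partner, and
sequencing reads are skewed toward it. For a heterozygous germline variant
the tumor-sample variant allele frequency (VAF) therefore shifts away from
the germline expectation of 0.5, and the *direction* of the shift

&nbsp;&nbsp;&nbsp;&nbsp;ΔVAF = VAF<sub>tumor</sub> − VAF<sub>normal</sub>

reveals the homolog of origin: variants on the over-represented homolog
shift up, variants on its partner shift down. Two variants shifting in the
same direction are in **cis**; in opposite directions, in **trans**. Unlike
read-backed phasing this works at arbitrary distances — up to whole
chromosomes — but only inside SCNA regions.

The pipeline is:

1. **ΔVAF + Fisher gate** — per site, compute VAFs and a two-sided Fisher
   exact test on the 2×2 table of (ref, alt) counts in (normal, tumor);
   only sites with p < 0.05 are ever phased.
2. **VAF-CBS** — circular binary segmentation of each chromosome's
   absolute-ΔVAF profile into constant-magnitude segments, after forcing
   breakpoints at inter-site gaps ≥ 1 Mb (the smoothing parameter).
3. **SCNA significance** — a segment is called a true SCNA by one of three
   null models: a hard cutoff on mean |ΔVAF| (≥ 0.14, the ~95th percentile
   of segment means in duplicated normal:normal pairs), a region-specific
   empirical null built from a panel of duplicated normals (significant at
   the ≥ 90th percentile of per-pair region means), or a fold-change rule
   (< 0.9 or > 1.1) on externally segmented copy ratios.
4. **Phase assignment** — within each significant segment, Fisher-significant
   heterozygous sites get hap 1 if ΔVAF > 0 and hap 0 if ΔVAF < 0; each
   segment yields one phase block (labels meaningful up to a global flip).

On top of this the package provides: merging with read-backed phase calls
(priority VAF > HapCUT2/phASER, the latter two only where they agree),
overall and pairwise discordance metrics between any two phasings, a
phase-aware compound-heterozygosity classifier (trans/cis/mono events from
CADD ≥ 15 damaging variants, ClinVar and LOF rules, compensatory /
non-compensatory variant-set calls), and a fully seeded simulator of paired
tumor:normal counts with known truth.

## Worked example

Simulate a tumor:normal pair (purity 0.6, mean depth 100, 200 heterozygous
sites on each of three 60 Mb chromosomes, one mono-allelic SCNA per
chromosome), then phase it:

```sh
vafphase simulate --seed 7 --out demo
# wrote demo.counts.tsv and demo.truth.tsv (600 sites)
vafphase phase --counts demo.counts.tsv --null-model hard_cutoff --out demo
# phased 153 variants in 5 block(s)
```

The significant rows of `demo.segments.seg` recover the three simulated
SCNA intervals (10–25 Mb on each chromosome; the first is split by a forced
gap breakpoint):

```text
sample  1  10833144  18181892  24  0.287874  true  hard_cutoff
sample  1  19329795  19382152   2  0.231043  true  hard_cutoff
sample  1  20461500  24948249  17  0.308643  true  hard_cutoff
sample  2  10121488  24907008  56  0.224361  true  hard_cutoff
sample  3  10062016  24512481  61  0.302227  true  hard_cutoff
```

`demo.phased.tsv` holds the calls — hap 1 marks the homolog
over-represented in the tumor:

```text
chrom  pos       ref  alt  block_id                 hap  source
1      10833144  A    G    VAF:1:10833144-18181892  1    VAF
1      11173898  A    G    VAF:1:10833144-18181892  0    VAF
1      11544104  A    G    VAF:1:10833144-18181892  1    VAF
```

Scoring against the simulator's truth (`vafphase.evaluate_phase_accuracy`):
153 of 600 sites phased, all 153 orientations correct up to the per-block
flip, and no site in diploid territory was phased. `demo.audit.tsv` records,
for every input site, its segment, test verdicts and why it was or was not
phased.

The same pipeline accepts real inputs: a counts TSV
(`chrom pos ref alt n_ref n_alt t_ref t_alt`), or a pair of VCFs with
per-sample allelic depths (`--normal-vcf`/`--tumor-vcf`), a panel of
duplicated-normal counts tables (`--panel`, for `--null-model
region_specific`), a SEG-like table with a `fold_change` column
(`--external-segments`, for `--null-model fold_change`), and a template VCF
to emit phased genotypes with `GT|PS` (`--template-vcf`). `vafphase
concord` compares two phased VCFs; `vafphase comphet` classifies per-gene
damaging-variant configurations from a phased VCF plus an annotation table.

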