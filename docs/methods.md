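# Methods

## Model

A tumor sample is modeled as a mixture of tumor cells (fraction *p*, the
purity) and normal cells. Consider a heterozygous germline variant whose
alternate allele lies on homolog with *c* copies per tumor cell while the
partner homolog has *c′* copies; normal cells carry one of each. The
expected tumor VAF is

    E[VAF_t] = (p·c + (1−p)) / (p·(c + c′) + 2(1−p))

and the expected total copy ratio (fold change) of the locus is
(p·(c+c′) + 2(1−p)) / 2. With balanced homologs (c = c′) the expected VAF
is 0.5 at any purity; any mono-allelic imbalance shifts it, with |ΔVAF|
increasing in purity and in the imbalance. A single-chromosome gain or loss
present in 20% of tumor cells gives fold changes of exactly 1.1 and 0.9 —
the bounds used by the fold-change significance rule.

The method's key assumption is that SCNAs are **mono-allelic** (they affect
one homolog). When a segment in fact mixes events on both homologs of
similar magnitude, the sign of ΔVAF no longer identifies a single homolog
and switch errors occur within the block; nothing in the data flags this,
which is why blocks are kept per-segment rather than stitched across a
chromosome.

## Per-site test

The two-sided Fisher exact test is computed on the table
[[n_ref, n_alt], [t_ref, t_alt]] under the hypergeometric null, using the
standard point-probability rule: the p-value sums the probabilities of all
tables with the observed margins whose point probability is at most that of
the observed table, with relative tie tolerance 1e−7. The implementation
evaluates the pmf via log-factorials and aggregates tails with a
sort/cumulative-sum pass, which also yields all p-values for a margin
triple at once (`fisher_pvalues_for_margins`); unit tests cross-check it
against `scipy.stats.fisher_exact` and against exact rational enumeration.
The test is standard (not mid-p), and no multiple-testing correction is
applied — the α = 0.05 gate is intentionally nominal, because a site must
*also* lie in a significant SCNA segment to be phased, and the pipeline
favors specificity. Significance is strict (p < α).

## Segmentation (VAF-CBS)

Heterozygous sites on a chromosome are first split at inter-site gaps
≥ `min_length_bp` (default 1,000,000 bp). Larger smoothing joins more
distant sites, yielding longer segments and more phased variants at the
cost of possibly bridging unobserved breakpoints; 1 Mb is the default
operating point, with 0.5–3 Mb the sensible range.

Within a gap-delimited unit, recursive circular binary segmentation is
applied to the absolute ΔVAF values. For a stretch x of length n the
statistic is the maximum over arc boundaries i < j of

    T(i,j) = |mean(x[i:j]) − mean(rest)| / (s·sqrt(1/m + 1/(n−m)))

with m = j − i and s the standard deviation of the whole stretch.
Significance of max T is assessed by permutation (default 1000 shuffles,
split when p < 0.01); a significant split divides the stretch at (i, j) and
recurses. Numerical choices:

- splits that would create a piece with fewer than `cbs_min_points`
  (default 2) sites are ineligible;
- zero-variance stretches never split (the statistic is undefined);
- argmax ties — including the exact complement-arc tie T(i,j) = T(0,i)∪(j,n)
  — are broken toward the smallest left boundary, then the smallest right
  boundary, with relative tolerance 1e−9;
- permutations are consumed in deterministic batches with early stopping
  once the exceedance count guarantees p ≥ α, so output is bit-reproducible
  for a given `seed` (default 17) while null stretches stay cheap;
- no pruning/undo pass is applied; the permutation gate plus recursion
  controls oversegmentation;
- segments span first to last member site only (no extrapolation), and a
  unit is the gap-delimited chunk (circularization is per chunk, not per
  chromosome).

Note the permutation gate bounds attainable p-values on small stretches:
with fewer than ~4 sites on a side of the change point, even a perfect step
cannot reach p < 0.01, so very small units are (correctly) left unsplit.

## SCNA significance

- **hard_cutoff** (default model): segment mean |ΔVAF| ≥ 0.14, inclusive.
  The 0.14 default corresponds to the empirical 95th percentile of segment
  means in duplicated normal:normal pairs — i.e. ~5% of pure-noise segments
  would pass — and is exposed as a parameter rather than re-derived.
- **region_specific**: the segment mean is ranked against the per-pair mean
  |ΔVAF| of the *same* interval in a panel of duplicated normals
  (significant at or above the 90th percentile, linear interpolation
  between order statistics). Panel means are computed per pair and then
  ranked; pooling all panel sites instead is available behind
  `panel_pooled`. Pairs whose own VAF-CBS profile contains a CNA-like
  segment (≥ 20 variants at mean |ΔVAF| ≥ 0.25 — screen thresholds chosen
  here, since contaminated pairs can otherwise only be found by inspection)
  are excluded as suspected tumor contamination of the normal. Segments
  with no panel coverage fall back to the hard cutoff (logged;
  `region_fallback`).
  The two percentiles are deliberately independent defaults: 95% motivates
  the 0.14 cutoff, 90% is the region-specific rank rule.
- **fold_change**: for externally segmented copy-ratio records,
  significant when fold change < 0.9 or > 1.1, strict on both bounds.

Single-variant segments are never significance-tested (a mean over one
noisy site is uninformative) and their sites stay unphased.

## Phase blocks and merging

Hap 1 = homolog over-represented in the tumor. A block needs ≥ 2 eligible
members; ΔVAF exactly 0 with a significant p (possible only through
pathological rounding) leaves a site unphased since its sign is undefined.
One block per significant segment — cross-segment stitching is out of
scope because the mono-allelic assumption is only asserted per event.

When merging sources, VAF calls win; sites phased only by HapCUT2 or only
by phASER are kept; sites phased by both are kept (as the HapCUT2 call)
only when the two sources agree on the site's orientation within their
common block, judged after anchoring on the first shared variant. When the
two read-backed blocks share fewer than two sites, orientation cannot be
compared and the call is kept (agreement is vacuous).

## Concordance metrics

Common blocks are the ≥ 2-site intersections of one block from each
method. Overall discordance = 1 − concordant/common, with orientations
aligned by declaring the first shared variant concordant (the anchor is
counted in both tallies; a majority-vote anchor would differ only when the
anchor itself is the errant call). Pairwise discordance classifies every
unordered in-block pair as discordant when the methods disagree on cis vs
trans, binned by half-open decade distance bins (10²…10⁸ bp) and by
minimum allele frequency ({singleton, <0.001, <0.01, <0.05, ≥0.05};
AF = 0 encodes a singleton, missing AF is reported as its own bin). Both
metrics are invariant to global flips of either method's labels and
symmetric in the two inputs. Per-pair features follow the standard set:
minimum read depth (per variant, the min of normal and tumor depth, since
the defining phrase does not pick a sample), segment size and mean |ΔVAF|,
ΔΔVAF, pair distance, Δ and minimum allele frequency.

## Compound heterozygosity

Damaging = CADD ≥ 15 (inclusive; missing scores are not damaging).
ClinVar-pathogenic = at least half of contributing submissions say
Pathogenic or Likely pathogenic. LOF variants qualify only at AF < 0.05 in
every supplied ancestry group. Gene events: trans when damaging variants
occupy both haplotypes — a homozygous damaging variant alone qualifies,
since both copies are altered (a design choice documented here, not
asserted of any external convention); cis when ≥ 2 phased damaging
variants share one haplotype with none on the other; mono for exactly one;
unresolved when phase cannot settle trans vs cis (such genes stay eligible
for the ClinVar/LOF and CADD tiers). Set scores: with range = max − min of
the individual variant scores, a set score ≤ min − 1.5·range is
compensatory and ≥ max + 1.5·range non-compensatory (inclusive); a zero
range is flagged degenerate, where any strict departure from the common
value classifies. Hierarchical grouping is first-match by precedence —
Trans > Cis > ClinVar/LOF > CADD > none, or Non-Compensatory >
Compensatory > ClinVar/LOF > CADD > none for the set-score scheme — and is
invariant to gene order and to hap flips. Conservation-model set scores
are inputs; only the classification thresholds are implemented here.
Indels, once counts exist, are treated exactly like SNVs (no
re-normalization is attempted), and whether their allelic depths are as
well calibrated as SNV depths is an open caveat of count-based input.

## Simulator

`simulate_pair` draws site positions uniformly per chromosome, assigns the
alternate allele to a homolog by fair coin, and samples normal counts as
Binomial(depth, 0.5) and tumor counts as Binomial(depth, E[VAF]) with
depths Poisson around the configured means (a negative-binomial option
with dispersion `nb_dispersion` exists for robustness checks). Binomial
read sampling at Poisson depth is the minimal model consistent with pure
read-sampling noise; the simulator does *not* model mapping or reference
bias, GC-dependent coverage, sequencing error, strand effects, subclonal
SCNAs, or depth changes proportional to copy number — so passing tests
demonstrate correctness of the inference under the stated noise model, not
robustness to real-data artifacts (on real data the Fisher gate is known
to be mildly inflated relative to this ideal).

Default study conditions: purity 0.6, mean depth 100×, 200 heterozygous
sites per 60 Mb chromosome (mean spacing 300 kb, comfortably inside the
1 Mb smoothing), and three mono-allelic SCNAs — copy-neutral LOH (2,0),
single-copy deletion (1,0), focal amplification (6,1), spanning 15 Mb
(~50 sites) each. The trio was chosen by an exact power analysis of the
Fisher gate at these depths: expected |ΔVAF| of 0.30 / 0.21 / 0.30 gives
per-region site-level power ≈ 0.99 / 0.85 / 0.99, i.e. an expected
in-region phased fraction ≈ 0.94, while diploid segments (mean |ΔVAF|
≈ 0.08 at 100×) stay far below the 0.14 cutoff. Null-panel simulations use
depth 80×. All draws flow through one `numpy` generator seeded by `seed`.

Problem sizes used by the test suite (5,000 sites for null calibration,
600 for recovery, margins ≤ 60 for the exact-test sweep, 200 series for
the split-point sweep) are chosen so the full suite completes in well
under a minute per criterion while keeping Monte-Carlo margins wide
relative to the asserted bounds.

## Known limitations

- Amplification vs deletion is not distinguished, and integer copy number,
  purity and ploidy are not estimated — only SCNA coordinates matter here.
- Phasing is impossible outside SCNA regions and unreliable when the
  mono-allelic assumption fails; block stitching, population priors and
  confidence scores for non-significant sites are deliberate non-goals.
- The region-specific null is only as good as the supplied panel's
  coverage; sparse panels silently fall back to the hard cutoff (logged).
- Counts are taken at face value: no realignment, left-normalization of
  indels, or strand-bias filtering is performed.
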