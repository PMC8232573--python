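# Methods

## Scope and data model

panelcnv detects copy-number variation from targeted capture-panel read
depth. The unit of coverage is the deduplicated overlapping-read count
per target region (a read counts once in every region it overlaps by
≥ 1 aligned base), not mean depth; counts are the natural unit for the
count-noise model, and mean depth is derivable when needed. Coordinates
are 0-based half-open throughout (BED convention); only the VCF writer
converts to 1-based. Contig names are taken verbatim — a BED/BAM naming
mismatch is an error rather than a silent "chr"-prefix fix.

When depth is extracted from alignments, retained reads are primary,
properly paired, mapped, not duplicate-flagged, with mapping quality
≥ 60. The panel's recurrent lesions live in an alteration catalog:
labelled entries with a scope of `region` (focal span, e.g. one gene),
`arm`, `whole_chromosome`, or `rearrangement` (categorical only —
translocations are never called from read depth here).

## Normalisation and baseline

**Library size.** Median-of-ratios factors against a geometric-mean
pseudo-reference (each region's reference is the geometric mean of
count + ½ across samples; a sample's factor is its median ratio to the
reference, factors rescaled to mean 1 and used as divisors). This
estimator is robust to CNVs occupying a minority of the panel, which is
exactly the case for arm-level events on a ~3 Mb design. If more than
half the regions contain a zero count the geometric reference is
uninformative and total-count factors are used instead.

**GC correction.** Regions are grouped into GC bins of width 0.02; each
value is scaled by (global median)/(bin median). Bins with fewer than
10 regions are merged with the occupied neighbour whose bin centre is
nearest (ties towards lower GC) before factors are computed; a bin with
median 0 gets factor 1. Binned-median scaling was chosen over LOESS
because it is deterministic, parameter-light and directly checkable
against an independent recomputation of the bin medians.

**Control selection.** R² is the squared Pearson correlation of
log2(normalised coverage + ½) between case and candidate; candidates
with R² ≥ 0.9 are accepted, best first. Selection runs on *fully
normalised* values even though it is conceptually the second step of
the pipeline: correlation on raw counts is dominated by library size
and would gate on sequencing yield rather than coverage shape. The log
scale stabilises variance across the panel's large dynamic range. At
least 3 controls are required (a median needs three points to resist
one outlier); an explicit `allow_best` override permits proceeding with
the top candidates when a batch has no good matches, and the failure
path always carries the full R² report.

**Baseline.** Per-region median and (unscaled) median absolute
deviation across accepted controls — robust in case the control pool
itself harbours CNVs. Regions whose baseline centre falls below 10
normalised counts are masked out of calling: the log-ratio of a
near-zero denominator is noise.

**Ratios.** log2((case + ½)/(centre + ½)). The pseudocount ½ appears
wherever a ratio or log is formed; its bias vanishes at panel depths
(hundreds of counts per region) and it removes all division-by-zero
corner cases. A case equal to its baseline centre gives exactly 0
regardless of pseudocount.

## Segmentation

Classical circular binary segmentation per chromosome. The statistic is
the max over circular arcs (width between `min_width` = 2 and
n − `min_width`) of |t| comparing arc mean vs complement mean with
pooled variance. Arcs wrapping the circle score identically to their
complements, and boundary arcs (i > 0, j = n) define the same partition
as (0, i], so only canonical contiguous arcs are enumerated; ties break
towards the smallest (i, j), making results platform-reproducible. Arcs
whose pooled variance cancels to zero score +inf when the means differ
(a noiseless step always splits) — this removes a 0/0 ambiguity; the
zero-variance guard is a relative tolerance on the variance numerator to
absorb floating-point cancellation.

A split is accepted when the permutation p-value
(1 + #{shuffles with max-|t| ≥ observed})/(1 + B) is below α = 0.01,
with B = 10 000 shuffles by default from a seeded generator; the
recursion then descends into the 2–3 implied parts. Permutations are
evaluated in vectorised batches; no tail approximation or hybrid
speedup is used because panels have at most a few thousand regions.
After recursion, an undo pass merges adjacent segments whose mean
difference is below `prune_sd` = 3 robust noise SDs, the noise SD being
1.4826 · median|successive difference|/√2 — the standard robust
estimator for array-like segmentation, insensitive to the events
themselves. Segments never cross chromosome boundaries; each chromosome
draws its permutation stream from a seed keyed on the chromosome name,
so a whole-genome run and a standalone run of one chromosome agree
exactly.

## Calling and annotation

CN = 2 · 2^(segment mean) against a diploid autosomal reference
(sex chromosomes use ploidy 2 by default with a config switch — the
panel content is autosome-dominated and explicit beats inferred).
Segments with CN ≥ 2.5 become duplications, CN ≤ 1.5 deletions; both
cutoffs are inclusive — the boundary has measure zero in practice and
inclusivity is documented and tested. The segment *mean* (not median)
feeds CN because it is the CBS-native statistic.

A catalog label is assigned when same-direction called segments cover
≥ 50 % of the entry's targeted bases (≥ 80 % for whole-chromosome
entries — aneuploidy should not be claimed from a focal hit). These
overlap thresholds are package choices, configurable; no published rule
defines when a called segment "is" del(5q) rather than a focal loss.
Calls in the wrong direction never receive a label; the mismatch is
recorded in the annotation report. Both layers — raw segments and
catalog labels — are always reported.

The implied clonal fraction uses the single-copy model: gain f = CN − 2,
loss f = 2 − CN, clipped to [0, 1] with an out-of-model flag for
multi-copy amplification or over-complete loss. Under this model the
2.5/1.5 cutoffs translate into a ~50 % clonality detection floor, which
is the mechanistic explanation for minor-clone aneuploidies being found
by karyotype but not by read depth.

## Concordance accounting

Each observed alteration carries the set of detecting techniques.
Cytogenetics = karyotype ∪ FISH; an alteration is "both" when NGS and at
least one cytogenetic technique saw it. The package ships, as packaged
TSV/JSON fixtures, the discordant-alteration tables and aggregate counts
of a published 138-patient myeloid cohort study; the concordant
alterations of that cohort exist only as an aggregate count, so the
cohort-level tally combines the tables with that aggregate. The
NGS-detected table has nine rows but one (a t(10;11) whose KMT2A
rearrangement was also flagged by break-apart FISH) categorises as
"both", reconciling the table with the study's count of eight NGS-only
alterations.

Display rounding follows the source tables: shares truncate at one
decimal (10/66 → 15.1 %), while chromosome and disease-level percents
round half-up (11/66 → 17 %). The source is not internally consistent
about rounding; this combination reproduces every printed number. The
study text's claim that six of nine low-clone cases fell below the FISH
cutoff matches no single threshold applied to the printed FISH values
(five cases are < 10 %, three < 7 %); the filter threshold is therefore
exposed as a parameter rather than forced to agree.

## Synthetic cohorts

The generator emulates the study conditions: ~3 Mb of targeted span
(2000 regions by default, log-normal lengths, Beta(12, 14) GC), a
catalog with the recurrent arm/chromosome lesions and per-gene entries,
and counts with expectation

μ_rs = N_s · p_r · g_s(gc_r) · CN_rs / 2,

where N_s is a log-normal library size anchored to ~300× median
deduplicated coverage (≈ 4 M retained read pairs for 2 × 101 bp reads),
p_r ∝ region length × log-normal capture efficiency (σ = 0.5),
g_s is a per-sample quadratic GC response normalised to mean 1, and
CN_rs = 2 + copies · f inside a spiked event. Counts are
negative-binomial via a gamma–Poisson mixture with shared dispersion
0.01 (≈ 10 % extra CV, typical of capture panels; the Poisson limit is
recovered at dispersion → 0). All generators are bit-reproducible given
(config, seed).

Cytogenetics emulators: karyotyping draws abnormal metaphases
Binomial(20, min(1, 1.3 · f)) — the 1.3 growth bias models
over-representation of the abnormal clone in culture — and reports at
≥ 2 abnormal metaphases (the conventional clonality rule); FISH draws
positive nuclei Binomial(200, min(1, f + 0.01)) with a 1 % technical
false-positive floor and probe-specific positivity cutoffs (7 %
single-locus/break-apart, 2.3 % dual-fusion).

What the simulation does *not* model: real per-region GC spectra and
mappability, batch effects beyond the control-selection gate, allele
fractions/LOH, read-level artefacts (counts are simulated directly, no
FASTQ/BAM synthesis), and translocation read pairs. Passing tests on
these cohorts therefore demonstrate the algorithm's arithmetic and its
clonality detection floor, not performance on any particular wet-lab
panel.

## Replicated experiments and problem sizes

The standing experiments (`panelcnv.experiments`) run 100 replicates at
the full study conditions — 2000 regions, ~300× coverage, eight
controls — with 500 permutations per CBS split test, a resolution that
comfortably supports the 0.01 split level while keeping a replicate
around two seconds. Observed under these conditions (seeded): a fully
clonal single-copy gain is called in ~100 % of replicates at CN ≈ 3.0
and a 30 % clone in ~0 % (CN ≈ 2.3); an 80 %-clonal del(12p) is
recovered and labelled in ~100 % of replicates with mean CN error
≈ 0.02; diploid samples average ≈ 0.01 called segments each. The unit
suite uses smaller panels (300–600 regions) and, for plumbing-level
recovery checks, mildly reduced dispersion so assertions sit far from
decision boundaries.

## Numerical and degenerate-input conventions

* Pseudocount ½ in every ratio/log; factors rescaled to mean 1.
* All-zero coverage vectors pass through GC correction unchanged; an
  all-zero *sample* is an error naming the sample.
* Flat profiles in control selection: identical flat profiles correlate
  perfectly (R² 1), non-identical ones score 0.
* A read overlapping two adjacent panel regions counts in both — the
  simplest reproducible rule; alternatives (fractional weighting) were
  rejected as unverifiable against any published behaviour.
* Vectors shorter than 2 · min_width are emitted as single segments;
  single-marker chromosomes are their own segment.
* Half-up vs truncation rounding as described under concordance.
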