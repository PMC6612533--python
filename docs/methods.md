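# Methods

This note documents the models implemented in `strexpand`, the assumptions
behind them, the parameters that matter, and what the synthetic data do and
do not establish about behaviour on real sequencing data.

## Motif canonicalisation and repeat purity

A repeat motif is represented by the lexicographically smallest string among
all cyclic rotations of its primitive unit and of the unit's reverse
complement. This makes evidence from either strand and any read phase
aggregate under one key (GGGAA, CCCTT and AAGGG are the same motif), and it
is idempotent.

Repeat purity of a read against a motif is the fraction of bases matching a
perfect, ungapped concatemer of the motif, maximised over the motif's phase
offset and both strands. Indels are not modelled: a read-length screen for
"consists of repetitions of a unit" does not need gapped alignment, and the
ungapped score keeps the operation linear in read length. Classification of
a read as an in-repeat read (IRR) searches unit lengths 2–6 and returns the
canonical motif of highest purity when that purity reaches the threshold;
ties go to the shorter primitive unit, then lexicographic order, so output
is deterministic.

Two implementation details are worth recording. For a fixed unit length k
the maximum purity over *all* 4^k units is obtained directly by taking the
modal base within each residue class (position mod k), so no unit
enumeration is needed; and a unit length can be skipped early using the
bound that purity ≥ t at period k forces the lag-k self-match fraction of
the read to be at least 1 − 2(1−t)·n/(n−k). Both are exact, and the fast
path is tested against a brute-force enumeration oracle.

Parameters:

* `purity_threshold` = 0.90. Sequencing error is elevated inside G-rich
  repeat tracts; 0.90 tolerates ~15 errors in a 150 bp read while a random
  read's best purity over units of length 2–6 stays far below it.
* `motif_lengths` = 2–6. Homopolymers are excluded by default: the RFC1
  locus sits in the A-rich tail of an Alu element, and poly-A tails across
  the genome would otherwise dominate genome-wide counts.

## Anchored in-repeat-read profiling

A read pair contributes evidence when exactly one mate classifies as an IRR
and the other mate is aligned with MAPQ ≥ `min_anchor_mapq` (default 50).
Pairs in which both mates are IRRs carry no confident position and are
excluded (counted in the log): they arise deep inside long tracts, where
the anchor has been lost. Anchor positions are clustered per motif by
single linkage with gap ≤ `cluster_gap` = 500 bp; anchors for one expansion
fall within a fragment length (~350 bp) of the locus on either flank, so
500 bp merges both flanks into one region while separating unrelated loci.

Counts are normalised to a reference depth of 30× (`norm = raw × 30/depth`)
so cohorts mixing library preparations and depths are comparable. Depth is
estimated as mean per-base coverage over user-supplied windows, which
should be interior windows clear of candidate loci and of reference edges.

Coordinates are 0-based half-open internally (BED interoperability) and
1-based inclusive in every report (`chr4:38887351-40463592` style).

## Case-control permutation ranking

The statistic per (motif, region) is mean(case) − mean(control) of
normalised counts; the alternative is one-sided because an expansion can
only inflate IRR counts. Regions are harmonised across samples by per-motif
interval union (within the same 500 bp gap), and samples without a region
contribute zero.

When the number of distinct case-label assignments C(n, k) is within the
permutation budget (default 10⁶) the null is enumerated exhaustively and
p = (#assignments with statistic ≥ observed)/C(n, k); since the statistic
is monotone in the case-subset sum, assignments are compared on subset sums.
Otherwise assignments are sampled with the add-one correction
p = (1 + exceedances)/(1 + n_perm), which cannot return zero. With 2 cases
and 31 controls the exhaustive floor is 1/528 ≈ 0.0019: the design can
rank loci (threshold p < 0.005 by default) but no locus can survive a
genome-wide Bonferroni correction — `adjust_genomewide` makes this explicit
with p_adj = min(1, p × n_tested). Type-I calibration is verified: over
2,000 exchangeable-null tests the rejection rate at α = 0.05 sits inside
the exact binomial interval.

## Locus screening and calls

For a cataloged locus, the screen collects reads overlapping the locus plus
IRR mates anchored within ±1,000 bp (a fragment length), records per-motif
purities (the support for ECDF-style cohort comparisons), and counts
reference-spanning reads: reads covering the whole tract, unclipped, MAPQ ≥
50, matching the reference motif concatemer with ≤ 10% mismatch. The call
mirrors flanking-PCR logic: in-repeat evidence without any spanning signal
is a homozygous pattern (no allele amplifies across); evidence plus
spanning signal is heterozygous; neither is no-expansion; no informative
reads at all is uninformative. Cohort-based calling (≥ 5 samples) also
requires the sample's count to exceed twice the cohort median for the
motif, so a motif noisy in everyone is not evidence. Expansion *size* is
deliberately not estimated: short reads cannot size alleles extending far
beyond the fragment length, and published tool comparisons show such
estimates are unreliable.

The off-target screen handles the sparse regime (e.g. exome off-target
coverage, median one read): with at least `min_reads` = 1 read at the
locus, it reports every motif supported by one sufficient-purity read,
plus "reference" when a read matches the reference motif; otherwise the
sample is uninformative. `consensus_call` reduces multiple detectors' calls
to the call shared by ≥ 4 of them (order-invariant).

## In-silico PCR

Both assays are deterministic functions of an allele's segment structure
`[(motif, n_units), ...]`, which represents compound alleles such as
(AAAAG)6-(AAAGG)n-(AAAAG)6 directly.

* Flanking PCR: per-allele product = flank_up + tract + flank_down, emitted
  only if ≤ `max_amplifiable` = 1,000 bp (a short extension cycle cannot
  produce multi-kilobase products). The default flanks sum to 198 bp so the
  55 bp reference tract yields the expected 253 bp product; the constants
  are configuration describing the assay, not inferred primer coordinates,
  and the output says so. Two products ⇒ two-non-expanded, one ⇒
  at-least-one-non-expanded, none ⇒ both-expanded; symmetric in allele
  order, and growing an allele never adds a product.
* Repeat-primed PCR: the repeat primer needs ≥ 3 consecutive perfect units
  (a minimal anchoring rule); peaks then appear at every unit boundary up
  to `max_extent` = 250 bp, so a long AAGGG expansion shows
  min(n_units, 250//5) = 50 peaks at 5 bp spacing. Stutter artefacts and
  trace rendering are out of scope.

## Haplotype-sharing MRCA dating

Model: all carriers descend independently from the most recent common
ancestor (star genealogy); the genetic length shared with the ancestral
haplotype on each side of the focal locus is Exponential with rate g per
Morgan, g = generations to the MRCA. Independence across carriers and
sides, no marker mutation, and an error-free map are assumed.

*Core haplotype.* The modal allele is taken per marker; the core is the
maximal interval around the focal marker on which the sharing fraction
strictly exceeds `majority` (default 0.5), with unanimity always
qualifying. The strict comparison matters: on biallelic markers the modal
fraction never drops below one half, so a non-strict rule would be vacuous
at the default threshold.

*Ancestral reconstruction by peeling.* Beyond the core, a plain per-marker
majority stops tracking the ancestral chromosome once few carriers still
share, which truncates exactly the longest shared segments and was observed
to bias ĝ upward by ~45% in parameter-recovery simulations. Instead the
consensus at each successive marker is taken among the carriers that still
match the consensus at every marker so far; recombined carriers drop out
and chance matches die within a couple of markers. Once fewer than two
carriers remain the ancestral allele is undefined and the surviving run is
right-censored there.

*Lengths and estimator.* Breakpoints are interval-censored by the marker
grid; the midpoint between the last matching and first mismatching marker
is used. With m uncensored one-sided lengths and total time on test S (all
lengths in Morgans, censored magnitudes included), the censored-exponential
MLE is ĝ = m/S, and 2gS is χ²(2m) exactly under type-II censoring, giving
the 95% interval [χ²(0.025, 2m)/2S, χ²(0.975, 2m)/2S]. Years = ĝ ×
`generation_time` (default 25 years, configurable; a convention, not an
estimate). Carriers mismatching the consensus at the focal marker itself
contribute zero lengths. If every length is censored no estimate is
produced. All modelling choices are echoed in the result's `model` string.

Empirical calibration on the package's own generative model: across
g ∈ {50, 200, 1000} × n ∈ {5, 20, 50} carriers, 100 replicates each, the
nominal-95% interval covers the true g in ≈ 94% of replicates and the
median relative error of ĝ at n = 20 is ≈ 0.11.

*Sub-haplotype clusters.* Carriers link when their pairwise shared segment
extends ≥ `margin_cm` = 0.5 cM beyond the core on either side; connected
components of ≥ 2 carriers form groups (A, B, ...), each re-dated on its
own consensus; carriers with no extended sharing are labelled N. Groups
share ancestry by construction, so group ages are not independent of the
cohort age.

*Allele frequency.* (n_het + 2·n_hom)/(2·n_individuals), rounded as
requested — e.g. 2 heterozygous + 1 homozygous carriers among 31
individuals gives 4/62 = 0.06.

## Synthetic data

*Reads.* Fragments (normal length, mean 350 sd 50, clipped to ≥ read
length) are drawn uniformly per haplotype at half the configured coverage;
uniform substitution errors at 0.5% by default (configurable upward to
emulate the elevated error seen in G-rich repeat reads). Aligner behaviour
is emulated rather than run: reads wholly in unique flank map with MAPQ 60;
reads wholly inside a non-reference repeat tract are "placed" at the locus
start with MAPQ 0 and full-length CIGAR (a fully soft-clipped record would
be invalid SAM; real aligners likewise drop MAPQ to 0 inside repeats);
boundary-straddling reads map with their repeat portion soft-clipped. The
reference embeds an exact (AAAAG)11 tract with an A-rich (80% A) 30 bp
tail immediately upstream, mirroring the Alu-tail context. A
`repeat_attenuation` factor (default 1.0; ~0.5 emulates PCR-based
libraries) thins fragments wholly inside the tract, reflecting the
PCR-versus-PCR-free coverage difference at expansions.

Not emulated: indels, PCR stutter, GC bias, multi-locus genomes, real
mapping ambiguity. Consequently, passing tests demonstrate the logic and
statistics of the pipeline under its stated model — they do not establish
sensitivity/specificity on real genomes, where mismapping and catalog
overlap add noise the simulator does not produce.

*Haplotypes.* Markers lie on a uniform grid (0.005 cM spacing, ±10 cM,
1 cM/Mb), a density typical of phased genome-wide SNPs; each carrier copies
the ancestral alleles between exponential left/right breakpoints and draws
background alleles (ancestral-allele frequency 0.5) outside. The map span
keeps edge censoring rare even at g = 50 (mean one-sided length 2 cM), and
the grid is fine enough that midpoint discretisation and chance matching
are negligible against the shortest segments at g = 1000 (mean 0.1 cM). A
truth record (g, ancestral vector, breakpoints) accompanies every matrix.

## Problem sizes and determinism

The shipped checks run the discovery screen at the full 2-case/31-control
design over a 20 kb reference at 30× (the locus and its evidence are local,
so a short reference exercises the same arithmetic as a chromosome), the
dating grid at 900 replicates, and the permutation calibration at 2,000
tests. Every stochastic component takes an explicit seed (spawned per
sample/replicate via NumPy `SeedSequence`), and all outputs carry tool
version, parameters, seeds and a configuration hash in their headers;
reruns with the same seed are byte-identical.

## Known limitations

* The permutation test treats samples as exchangeable; related individuals
  would need family-aware permutation, which is not implemented.
* The discovery statistic is a difference of means; rank-based alternatives
  would be more robust to a single extreme control.
* The dating model ignores marker mutation and phase error, and the star
  genealogy understates uncertainty when carriers are closely related —
  sub-haplotype clustering mitigates but does not remove this.
* The in-silico PCR models describe assay geometry (product sizes, ladder
  spacing and extent), not thermodynamics; they cannot predict primer
  failure or stutter.
* No allele-size estimation is attempted anywhere, by design.
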