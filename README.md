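# strexpand

Reference-free discovery of short tandem repeat (STR) expansions from
aligned short-read data, with the downstream analyses needed to take a
candidate from genome-wide screen to validated founder mutation:
case-control ranking, catalog locus screening, in-silico PCR, and
haplotype-sharing mutation dating.

The package is built around the genetics of CANVAS (cerebellar ataxia with
neuropathy and bilateral vestibular areflexia syndrome), which is caused by
biallelic expansion of a non-reference (AAGGG)n pentamer replacing the
(AAAAG)11 repeat in intron 2 of *RFC1*, inside the A-rich tail of an
AluSx3 element. Because the pathogenic motif is absent from the reference
genome, catalog-based STR genotypers cannot discover it; the discovery
signal used here is reference-free.

## Who it is for

Statistical geneticists and bioinformaticians who want a small, fully
tested, simulation-backed implementation of the expansion-discovery
workflow: to study its statistical behaviour (permutation floors,
Bonferroni limits, dating calibration), to prototype cohort designs, or to
teach how anchored in-repeat-read evidence works.

## The method

**Anchored in-repeat reads.** An expansion much longer than the read length
yields read pairs in which one mate lies wholly inside the repeat — an
in-repeat read (IRR), composed of one 2–6 bp motif and unmappable on its
own — while its mate maps confidently (MAPQ ≥ 50) in adjacent unique
sequence and anchors the pair. A read is classified as an IRR when its
repeat purity (fraction of bases matching a perfect motif concatemer,
maximised over phase and strand) reaches 0.90. Motifs are canonicalised to
the lexicographically smallest cyclic rotation of the primitive unit or its
reverse complement, so GGGAA, CCCTT and AAGGG evidence pools. Counts are
stratified by (motif, anchor region), depth-normalised to 30×.

**Case-control ranking.** For each (motif, region), the statistic is
mean(case) − mean(control) of normalised counts, tested one-sided by label
permutation — enumerated exhaustively whenever C(n_case+n_ctrl, n_case)
permutations fit the budget. With 2 cases and 31 controls the attainable
floor is p = 1/C(33,2) = 1/528 ≈ 0.0019, so genome-wide significance is
structurally impossible at that design; the p-values are used to *rank*
candidates, which are then intersected with prior intervals (e.g. a linkage
region).

**Validation stages.** A catalog screen collects per-sample in-repeat
evidence and reference-spanning read pairs at a known locus and calls
homozygous-pattern / heterozygous-pattern / no-expansion; flanking PCR and
repeat-primed PCR are modelled deterministically (a 253 bp reference
product; a saw-tooth ladder with 5 bp spacing that reads at most
~250 bp ≈ 50 units into the tract).

**Mutation dating.** Carriers of a single founder mutation share an
ancestral haplotype eroded by recombination. Under a star genealogy the
one-sided shared genetic lengths are Exponential(g) in Morgans, where g is
the generations to the most recent common ancestor (MRCA). With m
uncensored lengths and total time on test S (censored lengths contribute
their magnitude), the estimator is ĝ = m/S with exact χ² pivot interval
[χ²(0.025, 2m)/2S, χ²(0.975, 2m)/2S], converted to years at 25
years/generation. Sub-haplotype clusters that share beyond the core are
re-dated per group.

Every input the pipeline consumes can be generated by the built-in
simulators (paired-end reads with emulated aligner behaviour around a
configurable STR locus; phased carrier haplotypes with known MRCA age), so
the whole analysis is reproducible from a seed.

## Worked example

Simulate the discovery design — 2 homozygous (AAGGG)400 cases against 31
reference controls at 30×, 150 bp reads — and rank candidates:

```text
$ strexpand run-demo --out-dir demo --seed 7 --n-cases 2 --n-controls 31
planted locus: chr4:10001-10055
rank 1: AAGGG chr4:9720-10212 p=0.00189394 p_adj=0.00189
candidate table: demo/candidates.tsv
```

The planted expansion is the rank-1 candidate at the exhaustive-permutation
floor p = 1/528 ≈ 0.00189. The `p_adj` shown adjusts over the regions this
small simulation actually tested; adjusting over a realistic genome-wide
count of ≥ 528 regions gives p_adj = 1.0 — the 2-vs-31 design can rank but
never reach genome-wide significance.

In-silico PCR for a heterozygous carrier:

```text
$ strexpand insilico-pcr --genotype "AAAAGx11/AAGGGx400"
{ "flanking_pcr": { "product_sizes_bp": [253],
                    "interpretation": "at-least-one-non-expanded", ... },
  "repeat_primed_pcr": { "motif": "AAGGG",
    "ladders": [ {"n_peaks": 0, "spacing_bp": 5, ...},
                 {"n_peaks": 50, "spacing_bp": 5, ...} ] } }
```

One allele amplifies the 253 bp reference-length product (so at least one
allele is non-expanded); the expanded allele produces a repeat-primed
ladder of 50 peaks at 5 bp spacing, the assay's ~250 bp extension limit.

Dating a simulated carrier cohort (true g = 200, 20 carriers):

```python
>>> import strexpand as sx
>>> from strexpand.simulate import HapSimConfig, simulate_haplotypes
>>> matrix, truth = simulate_haplotypes(HapSimConfig(n_carriers=20, g=200, seed=7))
>>> core = sx.core_haplotype(matrix)
>>> est = sx.estimate_mrca(sx.shared_lengths(matrix, core))
>>> print(est.summary())
MRCA age estimate (haplotype sharing)
--------------------------------------------
generations to MRCA           273.7
95% CI (generations)   [193.7, 367.3]
years (x25/gen)              6842
95% CI (years)         [4842, 9183]
carrier haplotypes               20
one-sided lengths used           38
censored lengths                  2
total shared (Morgan)        0.1389
...
```

The 95% interval covers the true 200 generations; across the calibration
grid (g ∈ {50, 200, 1000} × n ∈ {5, 20, 50}) the interval covers truth in
about 94% of replicates.

Other subcommands: `simulate-reads`, `simulate-haplotypes`, `profile`,
`casecontrol`, `screen-locus`, `offtarget-screen`, `core-haplotype`,
`date-mrca`, `allele-freq`, `run-discovery` (YAML-configured). See
`strexpand --help`.

## Documentation

`docs/methods.md` describes the models, their assumptions, every tunable
parameter with its default and rationale, what the simulators do and do not
emulate, and known limitations.
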