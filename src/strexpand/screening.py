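"""Reference-catalog screening of a known STR locus for expansion evidence.

Once a candidate locus is known, each sample can be screened directly: reads
overlapping the locus and in-repeat mates anchored nearby are collected, and
their per-motif repeat purities form the evidence (the support of an
ECDF-style comparison across a cohort). The classifier layered on top mirrors
the flanking-PCR logic: the complete absence of reference-spanning read pairs
combined with in-repeat evidence indicates both alleles are expanded
(homozygous pattern), while spanning signal alongside in-repeat evidence
indicates a heterozygous carrier.

This module is a deliberately simple screen, not a reimplementation of the
catalog-based genotypers it conceptually replaces, and it makes no attempt to
estimate expansion size — short reads cannot size alleles that extend far
beyond the fragment length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .exceptions import (
    InvalidLocusError,
    InvalidParameterError,
    SampleLookupError,
)
from .motifs import (
    DEFAULT_PURITY_THRESHOLD,
    Motif,
    canonical_motif,
    repeat_purity,
)
from .profiling import DEFAULT_MIN_ANCHOR_MAPQ, AlignedRead, ReadPair

__all__ = [
    "STRLocus",
    "LocusScreenResult",
    "screen_locus",
    "call_expansion",
    "offtarget_screen",
    "consensus_call",
    "UNINFORMATIVE",
    "DEFAULT_EVIDENCE_WINDOW",
    "DEFAULT_MIN_EVIDENCE_READS",
]

UNINFORMATIVE = "uninformative"
DEFAULT_EVIDENCE_WINDOW = 1000  # covers a fragment length either side
DEFAULT_MIN_EVIDENCE_READS = 3
_SPANNING_MAX_MISMATCH = 0.10


@dataclass(frozen=True)
class STRLocus:
    """A cataloged STR locus (1-based inclusive reference coordinates)."""

    chrom: str
    start: int
    end: int
    ref_motif: Motif
    alt_motifs: tuple[Motif, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidLocusError(f"locus start {self.start} > end {self.end}")
        object.__setattr__(self, "ref_motif", canonical_motif(self.ref_motif))
        object.__setattr__(
            self, "alt_motifs", tuple(canonical_motif(m) for m in self.alt_motifs)
        )

    @property
    def motifs(self) -> tuple[Motif, ...]:
        return (self.ref_motif,) + self.alt_motifs


@dataclass
class LocusScreenResult:
    """Per-sample evidence collected at one locus.

    ``counts[m]`` is the number of informative reads with purity >= threshold
    for motif ``m``; ``purities[m]`` the per-read purity values (ECDF
    support); ``n_spanning`` the number of reads that span the whole
    reference tract with at most 10% mismatch to the reference allele.
    """

    sample: str
    locus: STRLocus
    counts: dict[str, int]
    purities: dict[str, list[float]] = field(default_factory=dict)
    n_spanning: int = 0
    n_informative: int = 0
    call: Optional[str] = None


def _read_overlaps(read: AlignedRead, chrom: str, start: int, end: int) -> bool:
    return (
        read.is_aligned
        and read.chrom == chrom
        and read.pos <= end
        and read.end >= start
    )


def _is_spanning(read: AlignedRead, locus: STRLocus, min_mapq: int) -> bool:
    if not read.is_aligned or read.chrom != locus.chrom or read.mapq < min_mapq:
        return False
    if "S" in read.cigar or "H" in read.cigar:
        return False
    if read.pos > locus.start or read.end < locus.end:
        return False
    offset = locus.start - read.pos
    tract_len = locus.end - locus.start + 1
    sub = read.seq[offset : offset + tract_len]
    if len(sub) < len(locus.ref_motif):
        return False
    return repeat_purity(sub, locus.ref_motif).value >= 1.0 - _SPANNING_MAX_MISMATCH


def screen_locus(
    pairs: Iterable[ReadPair],
    locus: STRLocus,
    motifs: Optional[Sequence[str]] = None,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    window: int = DEFAULT_EVIDENCE_WINDOW,
    min_anchor_mapq: int = DEFAULT_MIN_ANCHOR_MAPQ,
    sample: str = "sample",
    reference_length: Optional[int] = None,
) -> LocusScreenResult:
    """Collect per-motif in-repeat evidence for one sample at one locus.

    Informative reads are those overlapping the locus plus mates of reads
    anchored (mapq >= ``min_anchor_mapq``) within ``locus +/- window``. Each
    informative read contributes its purity against every screened motif and
    counts toward motifs for which purity >= ``purity_threshold``.
    """
    if locus.start < 1 or (
        reference_length is not None and locus.end > reference_length
    ):
        raise InvalidLocusError(
            f"locus {locus.chrom}:{locus.start}-{locus.end} outside reference bounds"
        )
    screened = tuple(
        canonical_motif(m) for m in (motifs if motifs is not None else locus.motifs)
    )
    win_start, win_end = locus.start - window, locus.end + window
    informative: list[AlignedRead] = []
    n_spanning = 0
    for pair in pairs:
        for read, mate in ((pair.mate1, pair.mate2), (pair.mate2, pair.mate1)):
            if _read_overlaps(read, locus.chrom, locus.start, locus.end):
                informative.append(read)
                if _is_spanning(read, locus, min_anchor_mapq):
                    n_spanning += 1
            elif (
                mate.is_aligned
                and mate.mapq >= min_anchor_mapq
                and _read_overlaps(mate, locus.chrom, win_start, win_end)
            ):
                # read anchored near the locus by its mate
                informative.append(read)
    counts: dict[str, int] = {m: 0 for m in screened}
    purities: dict[str, list[float]] = {m: [] for m in screened}
    for read in informative:
        if len(read.seq) == 0:
            continue
        for m in screened:
            if len(read.seq) < len(m):
                continue
            purity = repeat_purity(read.seq, m).value
            purities[m].append(purity)
            if purity >= purity_threshold:
                counts[m] += 1
    result = LocusScreenResult(
        sample=sample,
        locus=locus,
        counts=counts,
        purities=purities,
        n_spanning=n_spanning,
        n_informative=len(informative),
    )
    result.call = _basic_call(result, DEFAULT_MIN_EVIDENCE_READS)
    return result


def _basic_call(result: LocusScreenResult, min_evidence: int,
                baseline: Optional[Mapping[str, float]] = None) -> str:
    if result.n_informative == 0:
        return UNINFORMATIVE
    ref = result.locus.ref_motif
    evidence = False
    for motif, count in result.counts.items():
        if motif == ref:
            continue
        if count < min_evidence:
            continue
        if baseline is not None and count <= 2 * baseline.get(motif, 0.0):
            continue
        evidence = True
    if evidence and result.n_spanning == 0:
        return "homozygous-pattern"
    if evidence:
        return "heterozygous-pattern"
    return "no-expansion"


def call_expansion(
    cohort: Union[Mapping[str, LocusScreenResult], Sequence[LocusScreenResult]],
    sample: str,
    min_evidence: int = DEFAULT_MIN_EVIDENCE_READS,
) -> str:
    """Classify one sample against a cohort baseline.

    The cohort (>= 5 samples) provides per-motif median counts; a motif only
    counts as expansion evidence when the sample's count reaches
    ``min_evidence`` reads *and* exceeds twice the cohort median, guarding
    against motifs that are noisy across everyone. Calls are
    homozygous-pattern (evidence, no reference-spanning reads),
    heterozygous-pattern (evidence plus spanning reads), no-expansion, or
    uninformative (no informative reads at all).
    """
    if not isinstance(cohort, Mapping):
        cohort = {r.sample: r for r in cohort}
    if len(cohort) < 5:
        raise InvalidParameterError(
            f"cohort baseline requires >=5 samples, got {len(cohort)}"
        )
    if sample not in cohort:
        raise SampleLookupError(f"sample {sample!r} absent from cohort")
    motifs = sorted({m for r in cohort.values() for m in r.counts})
    baseline = {
        m: float(np.median([r.counts.get(m, 0) for r in cohort.values()]))
        for m in motifs
    }
    result = cohort[sample]
    call = _basic_call(result, min_evidence, baseline)
    result.call = call
    return call


def offtarget_screen(
    reads_at_locus: Sequence[Union[str, AlignedRead]],
    motifs: Sequence[str],
    ref_motif: Optional[str] = None,
    min_reads: int = 1,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> Union[set[str], str]:
    """Sparse-read screening (e.g. exome off-target reads at an intronic STR).

    With fewer than ``min_reads`` reads at the locus the sample is
    ``"uninformative"``. Otherwise the canonical motifs supported by at least
    one read of sufficient purity are returned, plus ``"reference"`` when a
    read matches the reference motif.
    """
    seqs = [r.seq if isinstance(r, AlignedRead) else r for r in reads_at_locus]
    if len(seqs) < min_reads:
        return UNINFORMATIVE
    observed: set[str] = set()
    for seq in seqs:
        for m in motifs:
            if len(seq) >= len(m) and repeat_purity(seq, m).value >= purity_threshold:
                observed.add(canonical_motif(m))
        if (
            ref_motif is not None
            and len(seq) >= len(ref_motif)
            and repeat_purity(seq, ref_motif).value >= purity_threshold
        ):
            observed.add("reference")
    return observed


def consensus_call(calls: Sequence[str], min_agree: int = 4) -> str:
    """Consensus over independent detectors: the call shared by at least
    ``min_agree`` of them, else ``"no-consensus"``. Order-invariant."""
    if not calls:
        raise InvalidParameterError("at least one detector call is required")
    if min_agree < 1:
        raise InvalidParameterError("min_agree must be >= 1")
    counter = Counter(calls)
    # deterministic: highest count first, lexicographic among equals
    best_call, best_count = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if best_count >= min_agree:
        return best_call
    return "no-consensus"
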