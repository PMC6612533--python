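"""Synthetic-data generators for every input the pipeline consumes.

Two generators are provided:

* paired-end short reads around a configurable STR locus, with an emulated
  aligner: reads wholly inside unique flank map with MAPQ 60; reads wholly
  inside a long non-reference repeat tract are placed at the locus start with
  MAPQ 0 (they are the in-repeat reads); reads straddling a tract boundary
  map with their repeat portion soft-clipped. This replaces running a real
  aligner and keeps tests hermetic; it is documented as a simplification of
  short-read aligner behaviour.

* phased carrier haplotype matrices with a known MRCA age: each carrier
  copies the ancestral allele vector around the focal marker up to left and
  right breakpoints drawn Exponential(rate g per Morgan), beyond which
  alleles are drawn from background frequencies. A truth record accompanies
  every matrix so parameter recovery can be scored exactly.

The defaults emulate the study conditions: 150 bp paired reads at 30x with
~350 bp fragments, a reference allele of (AAAAG)_11 sitting at the A-rich
3' tail of an Alu element, and pathogenic alleles that are long (AAGGG) or
compound (AAAAG)_6-(AAAGG)_n-(AAAAG)_6 expansions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidParameterError
from .dating import HaplotypeMatrix
from .pcr import AlleleModel
from .profiling import AlignedRead, ReadPair
from .screening import STRLocus

__all__ = [
    "ReadSimConfig",
    "HapSimConfig",
    "simulate_reference",
    "simulate_sample_reads",
    "simulate_haplotypes",
    "simulate_case_control_cohort",
    "REF_ALLELE",
    "AAGGG_EXPANSION",
    "COMPOUND_EXPANSION",
]

#: Reference allele at the locus: (AAAAG)_11, a 55 bp tract.
REF_ALLELE = AlleleModel(segments=(("AAAAG", 11),))
#: Canonical pathogenic allele used in examples: (AAGGG)_400.
AAGGG_EXPANSION = AlleleModel(segments=(("AAGGG", 400),))
#: Compound pathogenic allele: (AAAAG)_6-(AAAGG)_200-(AAAAG)_6.
COMPOUND_EXPANSION = AlleleModel(
    segments=(("AAAAG", 6), ("AAAGG", 200), ("AAAAG", 6))
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration for the paired-end read simulator."""

    reference_length: int = 20_000
    locus_offset: int = 10_000  # 0-based start of the STR tract
    ref_allele: AlleleModel = REF_ALLELE
    chrom: str = "chr4"
    coverage: float = 30.0
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    error_rate: float = 0.005
    a_rich_tail: int = 30  # A-rich bases upstream of the tract (Alu tail context)
    repeat_attenuation: float = 1.0  # <1 emulates PCR-based library dropout in-tract
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise InvalidParameterError("coverage must be positive")
        if self.fragment_mean <= self.read_length:
            raise InvalidParameterError("fragment_mean must exceed read_length")
        tract = self.ref_allele.tract_length
        if not (0 <= self.locus_offset and self.locus_offset + tract <= self.reference_length):
            raise ConfigurationError("locus does not fit inside the reference")
        if self.a_rich_tail > self.locus_offset:
            raise ConfigurationError("A-rich tail does not fit upstream of the locus")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def simulate_reference(config: ReadSimConfig) -> tuple[str, STRLocus]:
    """Seeded reference: random flanks, optional A-rich tail, exact STR tract.

    Returns the sequence and the locus record (1-based inclusive
    coordinates; BED conversion is ``start-1, end``). Deterministic for a
    fixed config.
    """
    rng = np.random.default_rng(config.seed)
    tract = config.ref_allele.tract_sequence()
    left_len = config.locus_offset - config.a_rich_tail
    left = _random_dna(rng, left_len)
    # A-rich Alu-tail context immediately upstream of the tract
    tail = (
        _BASES[np.where(rng.random(config.a_rich_tail) < 0.8, 0, rng.integers(0, 4, config.a_rich_tail))]
        .tobytes()
        .decode("ascii")
    )
    right = _random_dna(
        rng, config.reference_length - config.locus_offset - len(tract)
    )
    reference = left + tail + tract + right
    assert len(reference) == config.reference_length
    locus = STRLocus(
        chrom=config.chrom,
        start=config.locus_offset + 1,
        end=config.locus_offset + max(len(tract), 1),
        ref_motif=config.ref_allele.segments[0][0] if config.ref_allele.segments else "AAAAG",
    )
    return reference, locus


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(arr), size=n_err, replace=False)
    # substitute with a uniformly chosen *different* base
    shift = rng.integers(1, 4, size=n_err)
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr[pos] = _BASES[(lut[arr[pos]] + shift) % 4]
    return arr.tobytes().decode("ascii")


_RC = bytes.maketrans(b"ACGT", b"TGCA")


def _rc(seq: str) -> str:
    return seq.encode("ascii").translate(_RC)[::-1].decode("ascii")


def _align_read(
    a: int,
    b: int,
    hap_tract: tuple[int, int],
    ref_tract: tuple[int, int],
    tract_is_ref: bool,
    read_len: int,
) -> tuple[int, int, str]:
    """Emulated alignment of the haplotype interval [a, b) to the reference.

    Returns (0-based reference position, MAPQ, CIGAR).
    """
    ts, te = hap_tract
    rs, re_ = ref_tract
    shift = (te - ts) - (re_ - rs)  # alt tract length minus ref tract length
    if tract_is_ref:
        return a, 60, f"{read_len}M"
    if b <= ts:  # wholly in left flank
        return a, 60, f"{read_len}M"
    if a >= te:  # wholly in right flank
        return a - shift, 60, f"{read_len}M"
    if a >= ts and b <= te:  # wholly in-repeat: placed at locus start, MAPQ 0
        return rs, 0, f"{read_len}M"
    if a < ts:  # straddles left boundary: flank part maps, repeat part clipped
        return a, 60, f"{ts - a}M{b - ts}S"
    # straddles right boundary
    return re_, 60, f"{te - a}S{b - te}M"


def simulate_sample_reads(
    reference: str,
    locus: STRLocus,
    genotype: tuple[AlleleModel, AlleleModel],
    config: ReadSimConfig,
    sample: str = "sample",
    rng: Optional[np.random.Generator] = None,
) -> list[ReadPair]:
    """Simulate aligned paired-end reads for one diploid sample.

    Fragments are sampled from each haplotype at half the configured
    coverage; per-base substitution errors are applied; alignment is
    emulated as described in the module docstring. Pairs keep mate
    pointers and round-trip through SAM.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    read_len = config.read_length
    rs, re_ = locus.start - 1, locus.end  # 0-based half-open reference tract
    ref_tract_seq = reference[rs:re_]
    pairs: list[ReadPair] = []
    for hap_idx, allele in enumerate(genotype):
        tract_seq = allele.tract_sequence()
        hap = reference[:rs] + tract_seq + reference[re_:]
        tract_is_ref = tract_seq == ref_tract_seq
        ts, te = rs, rs + len(tract_seq)
        n_frag = int(round(config.coverage / 2 * len(hap) / (2 * read_len)))
        frag_lens = np.clip(
            rng.normal(config.fragment_mean, config.fragment_sd, n_frag),
            read_len,
            len(hap),
        ).astype(int)
        starts = rng.integers(0, len(hap) - frag_lens + 1)
        keep_drop = rng.random(n_frag)
        for i in range(n_frag):
            s, fl = int(starts[i]), int(frag_lens[i])
            e = s + fl
            if (
                config.repeat_attenuation < 1.0
                and not tract_is_ref
                and s >= ts
                and e <= te
                and keep_drop[i] >= config.repeat_attenuation
            ):
                continue  # PCR dropout of fragments wholly inside the repeat
            seq1 = _apply_errors(rng, hap[s : s + read_len], config.error_rate)
            seq2 = _apply_errors(rng, hap[e - read_len : e], config.error_rate)
            pos1, mq1, cg1 = _align_read(s, s + read_len, (ts, te), (rs, re_), tract_is_ref, read_len)
            pos2, mq2, cg2 = _align_read(e - read_len, e, (ts, te), (rs, re_), tract_is_ref, read_len)
            name = f"{sample}:h{hap_idx}:f{i}"
            mate1 = AlignedRead(
                chrom=config.chrom, pos=pos1 + 1, mapq=mq1, seq=seq1,
                cigar=cg1, is_reverse=False,
            )
            mate2 = AlignedRead(
                chrom=config.chrom, pos=pos2 + 1, mapq=mq2, seq=seq2,
                cigar=cg2, is_reverse=True,
            )
            pairs.append(ReadPair(name=name, mate1=mate1, mate2=mate2))
    return pairs


def simulate_case_control_cohort(
    config: ReadSimConfig,
    n_cases: int = 2,
    n_controls: int = 31,
    case_genotype: tuple[AlleleModel, AlleleModel] = (AAGGG_EXPANSION, AAGGG_EXPANSION),
    control_genotype: Optional[tuple[AlleleModel, AlleleModel]] = None,
) -> tuple[str, STRLocus, dict[str, list[ReadPair]], dict[str, str]]:
    """Simulate the discovery design: expanded cases versus reference controls.

    Returns (reference, locus, sample -> read pairs, sample -> label).
    Per-sample generators are spawned from the config seed so each sample is
    independent yet the whole cohort is reproducible.
    """
    reference, locus = simulate_reference(config)
    if control_genotype is None:
        control_genotype = (config.ref_allele, config.ref_allele)
    reads: dict[str, list[ReadPair]] = {}
    labels: dict[str, str] = {}
    children = np.random.SeedSequence(config.seed).spawn(n_cases + n_controls)
    idx = 0
    for i in range(n_cases):
        sample = f"case{i + 1}"
        reads[sample] = simulate_sample_reads(
            reference, locus, case_genotype, config, sample=sample,
            rng=np.random.default_rng(children[idx]),
        )
        labels[sample] = "case"
        idx += 1
    for i in range(n_controls):
        sample = f"control{i + 1}"
        reads[sample] = simulate_sample_reads(
            reference, locus, control_genotype, config, sample=sample,
            rng=np.random.default_rng(children[idx]),
        )
        labels[sample] = "control"
        idx += 1
    return reference, locus, reads, labels


@dataclass(frozen=True)
class HapSimConfig:
    """Configuration for the carrier-haplotype simulator."""

    n_carriers: int = 20
    g: float = 200.0  # generations to the MRCA
    map_span_cm: float = 10.0  # map extent on each side of the focal marker
    marker_spacing_cm: float = 0.005
    background_freq: float = 0.5  # frequency of the ancestral allele off-segment
    chrom: str = "chr4"
    focal_bp: int = 39_350_070
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise InvalidParameterError("g must be positive")
        if self.n_carriers < 1:
            raise InvalidParameterError("need at least one carrier")
        if self.map_span_cm < 1.0:
            raise InvalidParameterError("map must span >= 1 cM each side of the focal marker")
        if not (0 < self.background_freq < 1):
            raise InvalidParameterError("background_freq must be in (0, 1)")


def simulate_haplotypes(config: HapSimConfig) -> tuple[HaplotypeMatrix, dict]:
    """Simulate phased carrier haplotypes sharing a decaying ancestral segment.

    Markers sit on a uniform cM grid; each carrier copies the ancestral
    alleles within (-L_i, R_i) around the focal marker, with L_i, R_i drawn
    Exponential(rate g per Morgan); elsewhere alleles are Bernoulli draws of
    the ancestral allele at ``background_freq``. The truth record carries g,
    the ancestral vector, and the drawn breakpoints (in cM).
    """
    rng = np.random.default_rng(config.seed)
    n_side = int(round(config.map_span_cm / config.marker_spacing_cm))
    offsets = np.arange(-n_side, n_side + 1) * config.marker_spacing_cm
    n_markers = offsets.size
    focal = n_side
    bp = (config.focal_bp + np.round(offsets * 1e6 / config.cm_per_mb)).astype(int)
    markers = pd.DataFrame(
        {"chrom": config.chrom, "bp": bp, "cm": offsets}
    )
    ancestral = rng.integers(0, 2, size=n_markers).astype(np.int8)
    # breakpoints in Morgans -> cM
    left_bp = rng.exponential(1.0 / config.g, size=config.n_carriers) * 100.0
    right_bp = rng.exponential(1.0 / config.g, size=config.n_carriers) * 100.0
    share = (offsets[None, :] > -left_bp[:, None]) & (offsets[None, :] < right_bp[:, None])
    background = np.where(
        rng.random((config.n_carriers, n_markers)) < config.background_freq,
        ancestral[None, :],
        1 - ancestral[None, :],
    ).astype(np.int8)
    hap = np.where(share, ancestral[None, :], background)
    matrix = HaplotypeMatrix(
        markers=markers,
        haplotypes=hap,
        focal_index=focal,
        samples=[f"carrier{i + 1}" for i in range(config.n_carriers)],
    )
    truth = {
        "g": config.g,
        "ancestral": ancestral,
        "left_cm": left_bp,
        "right_cm": right_bp,
    }
    return matrix, truth
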