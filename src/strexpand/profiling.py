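"""Anchored in-repeat-read (IRR) profiling of aligned read pairs.

An expansion that is far longer than the read length leaves a distinctive
footprint in paired-end data: one mate lands inside the repeat tract and is
composed purely of the motif (the in-repeat read, unmappable on its own),
while its mate maps confidently in the adjacent unique sequence and anchors
the pair to a genomic position. Counting anchored IRRs stratified by motif
and anchor position, genome-wide and without a repeat catalog, is the
discovery signal used throughout this package.

Counts are depth-normalised to a common reference coverage so that samples
sequenced at different depths (or with PCR-based versus PCR-free libraries)
are comparable.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .motifs import (
    DEFAULT_MOTIF_LENGTHS,
    DEFAULT_PURITY_THRESHOLD,
    Motif,
    classify_irr,
    repeat_purity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "ReadPair",
    "AnchoredIRR",
    "SampleProfile",
    "find_anchored_irrs",
    "build_profile",
    "estimate_depth",
    "DEFAULT_MIN_ANCHOR_MAPQ",
    "DEFAULT_CLUSTER_GAP",
    "DEFAULT_REFERENCE_DEPTH",
]

DEFAULT_MIN_ANCHOR_MAPQ = 50
DEFAULT_CLUSTER_GAP = 500
DEFAULT_REFERENCE_DEPTH = 30.0

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignedRead:
    """One primary alignment record (or unaligned mate).

    ``pos`` is the 1-based leftmost aligned reference base, ``None`` when the
    read is unaligned.
    """

    chrom: Optional[str]
    pos: Optional[int]
    mapq: int
    seq: str
    cigar: str = ""
    is_reverse: bool = False

    @property
    def is_aligned(self) -> bool:
        return self.chrom is not None and self.pos is not None

    @property
    def aligned_length(self) -> int:
        """Number of reference bases consumed by the alignment."""
        if not self.cigar:
            return len(self.seq)
        return sum(
            int(n) for n, op in _CIGAR_RE.findall(self.cigar) if op in "MDN=X"
        )

    @property
    def end(self) -> Optional[int]:
        """1-based inclusive rightmost aligned base."""
        if not self.is_aligned:
            return None
        return self.pos + self.aligned_length - 1


@dataclass(frozen=True)
class ReadPair:
    name: str
    mate1: AlignedRead
    mate2: AlignedRead


@dataclass(frozen=True)
class AnchoredIRR:
    """One read pair contributing expansion evidence at an anchor position."""

    sample: str
    motif: Motif
    anchor_chrom: str
    anchor_pos: int  # 1-based leftmost aligned base of the anchor mate
    purity: float


@dataclass
class SampleProfile:
    """Per-sample table of depth-normalised anchored-IRR counts.

    ``counts`` has columns ``motif, chrom, start, end, raw_count,
    norm_count`` with 1-based inclusive region coordinates (the reporting
    convention; BED export converts to half-open).
    """

    sample: str
    depth: float
    counts: pd.DataFrame
    reference_depth: float = DEFAULT_REFERENCE_DEPTH


def find_anchored_irrs(
    pairs: Iterable[ReadPair],
    min_anchor_mapq: int = DEFAULT_MIN_ANCHOR_MAPQ,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    motif_lengths: Iterable[int] = DEFAULT_MOTIF_LENGTHS,
    sample: str = "sample",
) -> list[AnchoredIRR]:
    """Scan read pairs for anchored in-repeat reads.

    Emits one :class:`AnchoredIRR` per pair in which exactly one mate
    classifies as an IRR and the other mate is aligned with
    ``mapq >= min_anchor_mapq``. Pairs where both mates are IRRs carry no
    confident position; they are excluded and their count logged. The output
    is sorted canonically so it does not depend on input order.
    """
    motif_lengths = tuple(motif_lengths)
    out: list[AnchoredIRR] = []
    n_double_irr = 0
    for pair in pairs:
        m1 = classify_irr(pair.mate1.seq, motif_lengths, purity_threshold)
        m2 = classify_irr(pair.mate2.seq, motif_lengths, purity_threshold)
        if (m1 is None) == (m2 is None):
            if m1 is not None:
                n_double_irr += 1
            continue
        if m1 is not None:
            irr, anchor, motif = pair.mate1, pair.mate2, m1
        else:
            irr, anchor, motif = pair.mate2, pair.mate1, m2
        if not anchor.is_aligned or anchor.mapq < min_anchor_mapq:
            continue
        purity = repeat_purity(irr.seq, motif).value
        out.append(
            AnchoredIRR(
                sample=sample,
                motif=motif,
                anchor_chrom=anchor.chrom,
                anchor_pos=anchor.pos,
                purity=purity,
            )
        )
    if n_double_irr:
        logger.info(
            "%s: excluded %d pairs where both mates are in-repeat reads",
            sample,
            n_double_irr,
        )
    out.sort(key=lambda r: (r.anchor_chrom, r.anchor_pos, r.motif, -r.purity))
    return out


def _cluster_positions(positions: np.ndarray, gap: int) -> list[np.ndarray]:
    """Single-linkage 1-D clustering: split sorted positions at gaps > gap."""
    if len(positions) == 0:
        return []
    positions = np.sort(positions)
    breaks = np.nonzero(np.diff(positions) > gap)[0] + 1
    return np.split(positions, breaks)


def build_profile(
    irrs: Sequence[AnchoredIRR],
    depth: float,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
    reference_depth: float = DEFAULT_REFERENCE_DEPTH,
    sample: Optional[str] = None,
) -> SampleProfile:
    """Aggregate one sample's anchored IRRs into (motif, region) counts.

    Regions are formed per motif and chromosome by single-linkage clustering
    of anchor positions with inter-anchor gap <= ``cluster_gap``; the region
    span is the min..max anchor position. ``norm_count`` rescales the raw
    count to ``reference_depth``.
    """
    if depth <= 0:
        raise InvalidParameterError(f"depth must be positive, got {depth}")
    samples = {r.sample for r in irrs}
    if sample is None:
        if len(samples) > 1:
            raise InvalidParameterError(
                f"IRRs from multiple samples: {sorted(samples)}; pass sample="
            )
        sample = samples.pop() if samples else "sample"
    rows = []
    keyed: dict[tuple[str, str], list[int]] = {}
    for r in irrs:
        keyed.setdefault((r.motif, r.anchor_chrom), []).append(r.anchor_pos)
    scale = reference_depth / depth
    for (motif, chrom), positions in sorted(keyed.items()):
        for cluster in _cluster_positions(np.asarray(positions), cluster_gap):
            raw = len(cluster)
            rows.append(
                {
                    "motif": motif,
                    "chrom": chrom,
                    "start": int(cluster.min()),
                    "end": int(cluster.max()),
                    "raw_count": raw,
                    "norm_count": raw * scale,
                }
            )
    counts = pd.DataFrame(
        rows, columns=["motif", "chrom", "start", "end", "raw_count", "norm_count"]
    )
    return SampleProfile(
        sample=sample, depth=depth, counts=counts, reference_depth=reference_depth
    )


def estimate_depth(
    pairs: Iterable[ReadPair],
    windows: Sequence[tuple[str, int, int]],
) -> float:
    """Mean per-base coverage over sampling windows (0-based half-open).

    Windows should exclude candidate STR loci so repeat pile-ups do not skew
    the estimate. Returns 0 with a warning when no read overlaps any window.
    """
    if not windows:
        raise InvalidParameterError("at least one sampling window is required")
    total_window = sum(end - start for _, start, end in windows)
    if total_window <= 0:
        raise InvalidParameterError("sampling windows span zero bases")
    covered = 0
    n_reads = 0
    for pair in pairs:
        for read in (pair.mate1, pair.mate2):
            if not read.is_aligned:
                continue
            r_start0 = read.pos - 1
            r_end0 = r_start0 + read.aligned_length
            for chrom, w_start, w_end in windows:
                if chrom != read.chrom:
                    continue
                overlap = min(r_end0, w_end) - max(r_start0, w_start)
                if overlap > 0:
                    covered += overlap
                    n_reads += 1
    if n_reads == 0:
        warnings.warn("no reads overlap the depth-sampling windows; depth = 0")
        return 0.0
    return covered / total_window
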