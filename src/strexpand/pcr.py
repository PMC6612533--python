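"""Deterministic models of the two molecular validation assays.

Flanking PCR amplifies across the whole STR tract with primers in the unique
flanks: a product appears for an allele only while the amplicon stays within
the polymerase's reach (short extension cycles cannot produce multi-kilobase
products), so the *absence* of any product from a diploid sample is indirect
evidence that both alleles are expanded. With the default primer footprint
(flanks summing to 198 bp) the (AAAAG)_11 reference allele yields the
expected 253 bp product.

Repeat-primed PCR (RP-PCR) pairs one locus-specific primer with a primer that
anneals anywhere inside the repeat tract, producing a saw-tooth ladder whose
peak spacing equals the repeat unit length. The assay reads only ~250 bp into
the tract (50 pentamer units), so the ladder confirms motif presence but not
expansion size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .exceptions import InvalidParameterError, UndefinedInputError
from .motifs import canonical_motif, _check_alphabet

__all__ = [
    "AlleleModel",
    "PcrResult",
    "Ladder",
    "flanking_pcr",
    "rp_pcr_ladder",
    "DEFAULT_FLANK_UP",
    "DEFAULT_FLANK_DOWN",
    "DEFAULT_MAX_AMPLIFIABLE",
    "DEFAULT_MAX_EXTENT",
]

# Primer footprint constants: configuration chosen so the 55 bp reference
# tract amplifies to the expected 253 bp product (198 + 55).
DEFAULT_FLANK_UP = 99
DEFAULT_FLANK_DOWN = 99
DEFAULT_MAX_AMPLIFIABLE = 1000
DEFAULT_MAX_EXTENT = 250

_SEGMENT_RE = re.compile(r"^([ACGT]+)x(\d+)$")


@dataclass(frozen=True)
class AlleleModel:
    """Structure of one allele: ordered repeat segments plus flank lengths.

    ``segments`` is an ordered tuple of ``(unit, n_units)`` pairs, which
    represents both simple tracts like (AAGGG)_400 and compound tracts like
    (AAAAG)_6-(AAAGG)_n-(AAAAG)_6.
    """

    segments: tuple[tuple[str, int], ...]
    flank_up: int = 0
    flank_down: int = 0

    def __post_init__(self) -> None:
        for unit, n in self.segments:
            _check_alphabet(unit, "repeat unit")
            if n < 0:
                raise InvalidParameterError(f"negative unit count for {unit}: {n}")
        if self.flank_up < 0 or self.flank_down < 0:
            raise InvalidParameterError("flank lengths must be non-negative")

    @property
    def tract_length(self) -> int:
        return sum(len(unit) * n for unit, n in self.segments)

    @property
    def total_length(self) -> int:
        return self.flank_up + self.tract_length + self.flank_down

    def tract_sequence(self) -> str:
        return "".join(unit * n for unit, n in self.segments)

    @classmethod
    def parse(cls, text: str) -> "AlleleModel":
        """Parse e.g. ``"AAGGGx400"`` or ``"AAAAGx6-AAAGGx200-AAAAGx6"``."""
        segments = []
        for part in text.strip().split("-"):
            m = _SEGMENT_RE.match(part)
            if m is None:
                raise UndefinedInputError(
                    f"cannot parse allele segment {part!r}; expected e.g. 'AAGGGx400'"
                )
            segments.append((m.group(1), int(m.group(2))))
        return cls(segments=tuple(segments))

    def __str__(self) -> str:
        return "-".join(f"{unit}x{n}" for unit, n in self.segments)


@dataclass(frozen=True)
class PcrResult:
    """Flanking-PCR outcome for a diploid sample."""

    product_sizes: tuple[int, ...]
    interpretation: str  # two-non-expanded | at-least-one-non-expanded | both-expanded


@dataclass(frozen=True)
class Ladder:
    """RP-PCR ladder: peak positions in bases from the start of the tract."""

    peak_positions: tuple[int, ...]
    spacing: int


def flanking_pcr(
    diploid: tuple[AlleleModel, AlleleModel],
    flank_up: int = DEFAULT_FLANK_UP,
    flank_down: int = DEFAULT_FLANK_DOWN,
    max_amplifiable: int = DEFAULT_MAX_AMPLIFIABLE,
) -> PcrResult:
    """Simulate amplification across the STR for both alleles.

    Each allele's product is the primer-to-primer distance
    (``flank_up + tract + flank_down``); it is emitted only if it does not
    exceed ``max_amplifiable``. Interpretation is symmetric in allele order:
    two products mean neither allele is expanded, one product means at least
    one is not, and an empty product set means both alleles are expanded.
    """
    if flank_up < 0 or flank_down < 0:
        raise InvalidParameterError("flank lengths must be non-negative")
    if max_amplifiable <= 0:
        raise InvalidParameterError("max_amplifiable must be positive")
    products = tuple(
        sorted(
            flank_up + allele.tract_length + flank_down
            for allele in diploid
            if flank_up + allele.tract_length + flank_down <= max_amplifiable
        )
    )
    if len(products) == 2:
        interpretation = "two-non-expanded"
    elif len(products) == 1:
        interpretation = "at-least-one-non-expanded"
    else:
        interpretation = "both-expanded"
    return PcrResult(product_sizes=products, interpretation=interpretation)


def rp_pcr_ladder(
    allele: AlleleModel,
    motif: str,
    max_extent: int = DEFAULT_MAX_EXTENT,
    min_anchor_units: int = 3,
) -> Ladder:
    """Generate the repeat-primed PCR ladder for one allele.

    The repeat primer requires at least ``min_anchor_units`` consecutive
    perfect units of ``motif`` to anneal. If the allele carries such a run,
    peaks appear at every unit boundary up to
    ``min(tract run length, max_extent)``; spacing equals the motif length.
    Otherwise the ladder is empty.
    """
    target = canonical_motif(motif)
    k = len(canonical_motif(motif))
    # merge consecutive segments sharing the canonical motif into runs
    best_run = 0
    run = 0
    for unit, n in allele.segments:
        if canonical_motif(unit) == target:
            run += n
        else:
            best_run = max(best_run, run)
            run = 0
    best_run = max(best_run, run)
    if best_run < min_anchor_units:
        return Ladder(peak_positions=(), spacing=k)
    n_peaks = min(best_run, max_extent // k)
    return Ladder(peak_positions=tuple(k * i for i in range(1, n_peaks + 1)), spacing=k)
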