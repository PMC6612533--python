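"""Repeat-motif normalisation and per-read repeat-content classification.

Short tandem repeat (STR) evidence from opposite strands and from arbitrary
rotations of the same repeat unit must be pooled before any counting: a read
made of GGGAA repeats and a read made of CCCTT repeats both witness the same
AAGGG expansion. The canonical form used throughout the package is the
lexicographically smallest string among all cyclic rotations of the primitive
unit and of its reverse complement.

A read is an *in-repeat read* (IRR) when it consists (near-)entirely of
repetitions of a single 2–6 bp unit. Repeat content is quantified by an
ungapped purity score: the fraction of bases matching a perfect concatemer of
the unit, maximised over the unit's phase and over both strands. Homopolymers
are excluded from IRR classification by default because A-rich Alu tails —
exactly the sequence context in which the RFC1 expansion sits — would
otherwise flood genome-wide counts with poly-A evidence.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Optional

import numpy as np

from .exceptions import InvalidAlphabetError, UndefinedInputError

__all__ = [
    "Motif",
    "PurityScore",
    "reverse_complement",
    "primitive_root",
    "canonical_motif",
    "repeat_purity",
    "classify_irr",
    "DEFAULT_PURITY_THRESHOLD",
    "DEFAULT_MOTIF_LENGTHS",
]

#: A motif is represented as a plain canonical string (see :func:`canonical_motif`).
Motif = str

DEFAULT_PURITY_THRESHOLD = 0.90
DEFAULT_MOTIF_LENGTHS: range = range(2, 7)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")

# ASCII code -> base index (A,C,G,T -> 0..3, anything else -> 4)
_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


class PurityScore(NamedTuple):
    """Repeat purity of a sequence against one motif.

    ``value`` is the fraction of matching bases at the best phase/strand;
    ``phase`` is the unit offset (0..len(unit)-1) achieving it.
    """

    value: float
    phase: int


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise InvalidAlphabetError(f"{what} contains non-ACGT characters: {bad!r}")


def primitive_root(unit: str) -> str:
    """Smallest unit whose repetition reproduces ``unit`` (e.g. ATAT -> AT)."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit[:p] * (n // p) == unit:
            return unit[:p]
    return unit


def canonical_motif(unit: str) -> Motif:
    """Canonical form of a repeat unit.

    The primitive root of ``unit`` is taken first, then the lexicographic
    minimum over all cyclic rotations of the root and of its reverse
    complement. Idempotent by construction.

    >>> canonical_motif("GGGAA")
    'AAGGG'
    >>> canonical_motif("CCCTT")
    'AAGGG'
    >>> canonical_motif("AAAAA")
    'A'
    """
    if not unit:
        raise UndefinedInputError("motif unit must be non-empty")
    _check_alphabet(unit, "motif unit")
    root = primitive_root(unit)
    rc = reverse_complement(root)
    k = len(root)
    candidates = [root[i:] + root[:i] for i in range(k)]
    candidates += [rc[i:] + rc[:i] for i in range(k)]
    return min(candidates)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def repeat_purity(seq: str, motif: str) -> PurityScore:
    """Ungapped repeat purity of ``seq`` against ``motif``.

    The sequence is compared base-by-base with a perfect concatemer of the
    motif at every phase offset and on both strands; the best fraction of
    matching bases is returned. A perfect concatemer scores exactly 1.0
    regardless of how it is truncated. No indels are modelled.
    """
    if not motif:
        raise UndefinedInputError("motif must be non-empty")
    _check_alphabet(motif, "motif")
    if len(seq) < len(motif):
        raise UndefinedInputError(
            f"sequence length {len(seq)} is shorter than motif length {len(motif)}"
        )
    n, k = len(seq), len(motif)
    s = _encode(seq)
    best_matches = -1
    best_phase = 0
    for strand_unit in (motif, reverse_complement(motif)):
        m = _encode(strand_unit)
        template = np.tile(m, n // k + 2)
        for phase in range(k):
            matches = int((s == template[phase : phase + n]).sum())
            if matches > best_matches:
                best_matches = matches
                best_phase = phase
    return PurityScore(best_matches / n, best_phase)


def _best_unit_of_length(codes: np.ndarray, k: int) -> tuple[str, int]:
    """Exact maximiser of match count over *all* length-k units and phases.

    For a fixed unit length the optimal template simply places the modal base
    of each residue class (position mod k); ties resolve to the
    alphabetically first base, making the output deterministic. Maximising
    over all units subsumes both strands and all phases.
    """
    n = len(codes)
    residue = np.arange(n, dtype=np.intp) % k
    counts = np.bincount(residue * 5 + codes, minlength=5 * k).reshape(k, 5)[:, :4]
    best = counts.argmax(axis=1)
    matches = int(counts.max(axis=1).sum())
    unit = "".join("ACGT"[i] for i in best)
    return unit, matches


def classify_irr(
    seq: str,
    motif_lengths: Iterable[int] = DEFAULT_MOTIF_LENGTHS,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> Optional[Motif]:
    """Classify a read as an in-repeat read, returning its canonical motif.

    Returns the canonical motif of highest purity if that purity reaches
    ``purity_threshold``, else ``None``. Ties are broken by shorter primitive
    unit, then lexicographically smaller canonical form. Classification is
    strand-symmetric. Bases outside ACGT (e.g. N) never match.

    A cheap exact prefilter skips unit lengths that cannot reach the
    threshold: purity >= t at period k forces the lag-k self-match fraction of
    the read to be at least 1 - 2(1-t)n/(n-k).
    """
    if not seq:
        raise UndefinedInputError("cannot classify an empty sequence")
    lengths = sorted(set(int(k) for k in motif_lengths))
    if not lengths or lengths[0] < 1 or lengths[-1] > 6:
        raise InvalidAlphabetError(f"motif lengths must lie in [1, 6], got {lengths}")
    allowed = set(lengths)
    n = len(seq)
    codes = _BASE_LUT[_encode(seq)]
    best: Optional[tuple[int, int, str]] = None  # (-matches, root_len, canonical)
    for k in lengths:
        if k >= n:
            continue
        lag_bound = 1.0 - 2.0 * (1.0 - purity_threshold) * n / (n - k)
        if lag_bound > 0:
            self_match = float((codes[k:] == codes[:-k]).mean())
            if self_match < lag_bound:
                continue
        unit, matches = _best_unit_of_length(codes, k)
        root = primitive_root(unit)
        if len(root) not in allowed:
            continue
        key = (-matches, len(root), canonical_motif(root))
        if best is None or key < best:
            best = key
    if best is None:
        return None
    neg_matches, _root_len, canonical = best
    if -neg_matches >= purity_threshold * n - 1e-9:
        return canonical
    return None
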