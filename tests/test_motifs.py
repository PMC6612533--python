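"""Motif canonicalisation and per-read repeat-content classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strexpand.exceptions import InvalidAlphabetError, UndefinedInputError
from strexpand.motifs import (
    canonical_motif,
    classify_irr,
    primitive_root,
    repeat_purity,
    reverse_complement,
)
from conftest import random_dna

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_canonical(unit: str) -> str:
    """Independent enumeration oracle: primitive root via doubling trick, then
    the lexicographic minimum over rotations of the root and its reverse
    complement."""
    period = (unit + unit).index(unit, 1)
    root = unit[:period]
    rc = "".join(_COMP[c] for c in reversed(root))
    rotations = [root[i:] + root[:i] for i in range(len(root))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def oracle_classify(seq, lengths, threshold):
    """Brute force over every unit of the allowed lengths, scoring each with
    repeat_purity (which already scans phases and strands)."""
    allowed = set(lengths)
    best = None
    for k in lengths:
        for unit in itertools.product("ACGT", repeat=k):
            unit = "".join(unit)
            if len(primitive_root(unit)) not in allowed:
                continue
            matches = round(repeat_purity(seq, unit).value * len(seq))
            key = (-matches, len(primitive_root(unit)), canonical_motif(unit))
            if best is None or key < best:
                best = key
    neg_matches, _, canon = best
    return canon if -neg_matches >= threshold * len(seq) else None


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "unit,expected",
        [("AAGGG", "AAGGG"), ("GGGAA", "AAGGG"), ("CCCTT", "AAGGG"), ("AAAAA", "A")],
    )
    def test_examples(self, unit, expected):
        assert canonical_motif(unit) == expected

    def test_exhaustive_invariance_short_units(self):
        """Rotation and reverse-complement invariance, exhaustive for lengths 1-4."""
        for k in range(1, 5):
            for unit in map("".join, itertools.product("ACGT", repeat=k)):
                canon = canonical_motif(unit)
                assert canon == oracle_canonical(unit)
                rc = reverse_complement(unit)
                for i in range(k):
                    assert canonical_motif(unit[i:] + unit[:i]) == canon
                    assert canonical_motif(rc[i:] + rc[:i]) == canon

    def test_sampled_invariance_long_units(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            k = int(rng.integers(5, 7))
            unit = "".join("ACGT"[i] for i in rng.integers(0, 4, k))
            canon = canonical_motif(unit)
            assert canon == oracle_canonical(unit)
            rot = int(rng.integers(0, k))
            assert canonical_motif(unit[rot:] + unit[:rot]) == canon
            assert canonical_motif(reverse_complement(unit)) == canon

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_idempotent(self, unit):
        canon = canonical_motif(unit)
        assert canonical_motif(canon) == canon

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            canonical_motif("AANGG")
        with pytest.raises(UndefinedInputError):
            canonical_motif("")


class TestRepeatPurity:
    @pytest.mark.parametrize("phase", range(5))
    def test_perfect_concatemer_any_truncation(self, phase):
        seq = ("AAGGG" * 31)[phase : phase + 150]
        assert repeat_purity(seq, "AAGGG").value == 1.0

    def test_fifteen_errors_give_090(self):
        seq = list("AAGGG" * 30)
        for i in range(0, 150, 10):
            seq[i] = "C"  # C never occurs in AAGGG, so every edit mismatches
        assert repeat_purity("".join(seq), "AAGGG").value == pytest.approx(0.90)

    def test_unrelated_periodic_sequence_scores_low(self):
        assert repeat_purity("ACGT" * 37 + "AC", "AAGGG").value < 0.7

    def test_strand_symmetry(self):
        seq = random_dna(90, seed=5)
        assert (
            repeat_purity(seq, "AAGGG").value
            == repeat_purity(reverse_complement(seq), "AAGGG").value
        )

    def test_too_short_input(self):
        with pytest.raises(UndefinedInputError):
            repeat_purity("AC", "AAGGG")


class TestClassifyIrr:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAGGG" * 30, "AAGGG"),
            ("AAAAG" * 30, "AAAAG"),
            ("CCCTT" * 30, "AAGGG"),  # opposite strand evidence pools
            ("A" * 150, None),  # homopolymers excluded by default
        ],
    )
    def test_examples(self, seq, expected):
        assert classify_irr(seq) == expected

    def test_random_read_is_not_irr(self):
        assert classify_irr(random_dna(150, seed=0)) is None

    def test_empty_sequence(self):
        with pytest.raises(UndefinedInputError):
            classify_irr("")

    def test_strand_symmetric(self):
        for seed in range(5):
            seq = random_dna(60, seed=seed)
            noisy = seq[:20] + "AAGGG" * 8  # partial repeat content
            assert classify_irr(noisy) == classify_irr(reverse_complement(noisy))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """The fast classifier must agree with exhaustive unit enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 45))
        if seed % 2:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        else:
            unit = ["AAGGG", "AAAGG", "AT", "ACG"][seed % 4]
            seq = (unit * (n // len(unit) + 1))[:n]
            arr = list(seq)
            for i in rng.integers(0, n, size=n // 10):
                arr[i] = "ACGT"[rng.integers(0, 4)]
            seq = "".join(arr)
        lengths = range(2, 5)
        assert classify_irr(seq, lengths, 0.9) == oracle_classify(seq, lengths, 0.9)

    def test_noisy_expansion_read_still_classifies(self):
        rng = np.random.default_rng(3)
        seq = list("AAGGG" * 30)
        for i in rng.choice(150, size=10, replace=False):
            seq[i] = "ACGT"[rng.integers(0, 4)]
        assert classify_irr("".join(seq)) == "AAGGG"
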