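"""Permutation test, candidate ranking, interval annotation, adjustment."""

import numpy as np
import pandas as pd
import pytest

from strexpand.casecontrol import (
    adjust_genomewide,
    intersect_candidates,
    permutation_test,
    rank_candidates,
)
from strexpand.exceptions import ConfigurationError, InvalidParameterError
from strexpand.profiling import SampleProfile


def make_profile(sample, count, motif="AAGGG", start=9800, end=10200, depth=30.0):
    rows = []
    if count > 0:
        rows.append({"motif": motif, "chrom": "chr4", "start": start, "end": end,
                     "raw_count": count, "norm_count": float(count)})
    counts = pd.DataFrame(
        rows, columns=["motif", "chrom", "start", "end", "raw_count", "norm_count"]
    )
    return SampleProfile(sample=sample, depth=depth, counts=counts)


class TestPermutationTest:
    def test_two_cases_against_31_zero_controls(self):
        """Only the true labelling attains the maximum, so p = 1/C(33,2)."""
        assert permutation_test([5, 6], [0.0] * 31) == pytest.approx(1 / 528)

    def test_all_equal_counts(self):
        assert permutation_test([3.0, 3.0], [3.0] * 31) == 1.0

    def test_one_sided_null_direction(self):
        assert permutation_test([0.0, 0.0], [10.0] * 31) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            permutation_test([], [1.0])
        with pytest.raises(InvalidParameterError):
            permutation_test([1.0], [])

    def test_exhaustive_and_sampled_agree(self):
        rng = np.random.default_rng(12)
        case = rng.normal(1.0, 1.0, size=4)
        ctrl = rng.normal(0.0, 1.0, size=6)
        p_exact = permutation_test(case, ctrl, n_perm=10**6)  # C(10,4)=210, exhaustive
        n_perm = 20_000
        p_mc = permutation_test(case, ctrl, n_perm=n_perm, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / n_perm

    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [
            permutation_test(x[:2], x[2:])
            for x in (rng.normal(size=12) for _ in range(300))
        ]
        assert 0.35 < np.median(ps) < 0.65


class TestRankCandidates:
    def test_planted_locus_ranks_first(self):
        profiles = [make_profile("case1", 10), make_profile("case2", 12)]
        profiles += [make_profile(f"ctrl{i}", 0) for i in range(31)]
        labels = {p.sample: ("case" if p.sample.startswith("case") else "control")
                  for p in profiles}
        df = rank_candidates(profiles, labels, seed=1)
        assert len(df) == 1
        top = df.iloc[0]
        assert (top.motif, top["rank"]) == ("AAGGG", 1)
        assert top.p_value == pytest.approx(1 / 528)

    def test_region_harmonisation_unifies_offset_regions(self):
        profiles = [
            make_profile("case1", 10, start=9800, end=10200),
            make_profile("case2", 12, start=9900, end=10300),
        ]
        profiles += [make_profile(f"ctrl{i}", 0) for i in range(31)]
        labels = {p.sample: ("case" if p.sample.startswith("case") else "control")
                  for p in profiles}
        df = rank_candidates(profiles, labels, seed=1)
        assert len(df) == 1
        assert (df.iloc[0].start, df.iloc[0].end) == (9800, 10300)

    def test_shuffled_labels_remove_signal(self):
        """When the case labels land on two unexpanded samples, the planted
        locus must not reach p < 0.005."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            profiles = [make_profile("exp1", 10), make_profile("exp2", 12)]
            profiles += [make_profile(f"ctrl{i}", 0) for i in range(31)]
            names = [p.sample for p in profiles]
            fake_cases = set(rng.choice(names[2:], size=2, replace=False))
            labels = {n: ("case" if n in fake_cases else "control") for n in names}
            df = rank_candidates(profiles, labels, seed=seed)
            assert len(df) == 0

    def test_missing_label_is_configuration_error(self):
        profiles = [make_profile("a", 1), make_profile("b", 0)]
        with pytest.raises(ConfigurationError):
            rank_candidates(profiles, {"a": "case"})

    def test_single_class_is_configuration_error(self):
        profiles = [make_profile("a", 1), make_profile("b", 0)]
        with pytest.raises(ConfigurationError):
            rank_candidates(profiles, {"a": "case", "b": "case"})


class TestIntersectAndAdjust:
    @pytest.fixture
    def candidates(self):
        df = pd.DataFrame(
            [
                {"motif": "AAGGG", "chrom": "chr4", "start": 39350045,
                 "end": 39350095, "statistic": 40.0, "p_value": 1 / 528, "rank": 1},
                {"motif": "AAGGG", "chrom": "chr5", "start": 39350045,
                 "end": 39350095, "statistic": 10.0, "p_value": 0.004, "rank": 2},
            ]
        )
        df.attrs["n_tested_regions"] = 2
        return df

    def test_linkage_interval_annotation(self, candidates):
        out = intersect_candidates(
            candidates, [("linkage", "chr4", 38887351, 40463592)]
        )
        assert list(out.annotations) == ["linkage", ""]

    def test_chromosome_name_normalisation(self, candidates):
        out = intersect_candidates(candidates, [("linkage", "4", 38887351, 40463592)])
        assert out.annotations.iloc[0] == "linkage"

    def test_abutting_interval_does_not_overlap(self, candidates):
        # interval ends exactly where the candidate starts (half-open arithmetic)
        out = intersect_candidates(
            candidates, [("left", "chr4", 39350000, 39350044)]
        )
        assert out.annotations.iloc[0] == ""

    def test_bonferroni_examples(self, candidates):
        out = adjust_genomewide(candidates, n_tested_regions=1000)
        assert out.p_adjusted.iloc[0] == 1.0  # 1000/528 capped at 1
        tiny = candidates.copy()
        tiny["p_value"] = [1e-8, 0.5]
        out = adjust_genomewide(tiny, n_tested_regions=1000)
        assert out.p_adjusted.iloc[0] == pytest.approx(1e-5)
        one = candidates.iloc[:1].copy()
        one["p_value"] = [0.5]
        assert adjust_genomewide(one, 1).p_adjusted.iloc[0] == 0.5

    def test_adjust_requires_enough_regions(self, candidates):
        with pytest.raises(InvalidParameterError):
            adjust_genomewide(candidates, n_tested_regions=1)
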