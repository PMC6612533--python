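"""Core haplotype, shared-length extraction, MRCA estimation, subgrouping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strexpand.dating import (
    HaplotypeMatrix,
    allele_frequency,
    cluster_subhaplotypes,
    core_haplotype,
    estimate_mrca,
    shared_lengths,
)
from strexpand.exceptions import (
    CannotEstimateError,
    DegenerateCoreError,
    InvalidParameterError,
)
from strexpand.simulate import HapSimConfig, simulate_haplotypes


def toy_matrix(rows, cm=None, focal=None, bp=None):
    rows = np.asarray(rows, dtype=np.int8)
    n_markers = rows.shape[1]
    if cm is None:
        cm = np.arange(n_markers) * 0.1
    if bp is None:
        bp = 1_000_000 + np.arange(n_markers) * 100_000
    markers = pd.DataFrame({"chrom": "chr4", "bp": bp, "cm": cm})
    return HaplotypeMatrix(
        markers=markers, haplotypes=rows,
        focal_index=n_markers // 2 if focal is None else focal,
    )


class TestCoreHaplotype:
    def test_shared_block_recovered(self):
        """Six haplotypes identical at markers 3-7 around focal 5, discordant
        outside (3 vs 3 split keeps the modal fraction at exactly one half,
        which is not a strict majority)."""
        inner = [1] * 5
        rows = []
        for i in range(6):
            outer_l = [1, 1, 1] if i < 3 else [0, 0, 0]
            outer_r = [0, 0, 0] if i < 3 else [1, 1, 1]
            rows.append(outer_l + inner + outer_r)
        core = core_haplotype(toy_matrix(rows, focal=5))
        assert (core.left_index, core.right_index) == (3, 7)
        assert list(core.alleles[3:8]) == [1] * 5

    def test_full_sharing_spans_whole_map(self):
        rows = [[1] * 11] * 4
        core = core_haplotype(toy_matrix(rows, focal=5))
        assert (core.left_index, core.right_index) == (0, 10)
        assert core.bp_span == 10 * 100_000 + 1

    def test_unanimity_threshold_stops_at_single_discordance(self):
        rows = [[1] * 11 for _ in range(6)]
        rows[0][4] = 0  # one discordant carrier at marker 4
        rows[0][8] = 0
        core = core_haplotype(toy_matrix(rows, focal=5), majority=1.0)
        assert (core.left_index, core.right_index) == (5, 7)

    def test_core_always_contains_focal(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            rows = rng.integers(0, 2, size=(6, 11))
            rows[:, 5] = 1
            core = core_haplotype(toy_matrix(rows, focal=5))
            assert core.left_index <= 5 <= core.right_index

    def test_raising_majority_never_widens_core(self):
        rng = np.random.default_rng(8)
        rows = rng.integers(0, 2, size=(8, 21))
        rows[:, 8:13] = 1
        m = toy_matrix(rows, focal=10)
        widths = []
        for majority in (0.5, 0.7, 0.9, 1.0):
            core = core_haplotype(m, majority=majority)
            widths.append(core.right_index - core.left_index)
        assert widths == sorted(widths, reverse=True)

    def test_degenerate_core(self):
        with pytest.raises(DegenerateCoreError):
            core_haplotype(toy_matrix([[0, 1, 0], [1, 0, 1]], focal=1))


class TestSharedLengths:
    def test_midpoint_rule(self):
        # markers at cm -0.4,-0.2,0,1,2 ; focal at index 2
        cm = np.array([-0.4, -0.2, 0.0, 1.0, 2.0])
        ancestral = np.ones(5, dtype=np.int8)
        rows = [
            [1, 1, 1, 1, 0],  # match at 1 cM, mismatch at 2 cM -> right 1.5
            [1, 0, 1, 1, 1],  # immediate left mismatch 0.2 away -> left 0.1
        ]
        m = toy_matrix(rows, cm=cm, focal=2)
        out = shared_lengths(m, ancestral)
        assert out.right_cm.iloc[0] == pytest.approx(1.5)
        assert not out.right_censored.iloc[0]
        assert out.left_cm.iloc[1] == pytest.approx(0.1)

    def test_map_edge_is_censored(self):
        cm = np.array([-0.4, -0.2, 0.0, 1.0, 2.0])
        m = toy_matrix([[1] * 5, [1] * 5], cm=cm, focal=2)
        out = shared_lengths(m, np.ones(5, dtype=np.int8))
        assert out.right_censored.all() and out.left_censored.all()
        assert out.right_cm.iloc[0] == pytest.approx(2.0)
        assert out.left_cm.iloc[0] == pytest.approx(0.4)

    def test_focal_mismatch_gives_zero_lengths(self):
        cm = np.array([0.0, 0.5, 1.0])
        m = toy_matrix([[1, 0, 1], [1, 1, 1]], cm=cm, focal=1)
        out = shared_lengths(m, np.ones(3, dtype=np.int8))
        assert (out.left_cm.iloc[0], out.right_cm.iloc[0]) == (0.0, 0.0)


class TestEstimateMrca:
    def test_closed_form_single_carrier(self):
        est = estimate_mrca([(0.01, 0.01)])  # 1 cM each side, in Morgans
        assert est.g_hat == pytest.approx(100.0)
        assert est.years == pytest.approx(2500.0)
        assert est.ci_low < est.g_hat < est.ci_high

    def test_scale_equivariance(self):
        lengths = [(0.01, 0.02), (0.005, 0.03)]
        doubled = [(2 * a, 2 * b) for a, b in lengths]
        assert estimate_mrca(doubled).g_hat == pytest.approx(
            estimate_mrca(lengths).g_hat / 2
        )

    def test_ci_matches_chi_square_pivot(self):
        est = estimate_mrca([(0.01, 0.01)])
        assert est.ci_low == pytest.approx(stats.chi2.ppf(0.025, 4) / 0.04)
        assert est.ci_high == pytest.approx(stats.chi2.ppf(0.975, 4) / 0.04)

    def test_all_censored_cannot_estimate(self):
        df = pd.DataFrame(
            {"sample": ["a"], "left_cm": [2.0], "right_cm": [2.0],
             "left_censored": [True], "right_censored": [True]}
        )
        with pytest.raises(CannotEstimateError):
            estimate_mrca(df)

    def test_invalid_generation_time(self):
        with pytest.raises(InvalidParameterError):
            estimate_mrca([(0.01, 0.01)], generation_time=0)

    def test_summary_mentions_key_quantities(self):
        text = estimate_mrca([(0.01, 0.01)]).summary()
        assert "generations" in text and "95% CI" in text

    def test_recovery_on_simulated_cohorts(self):
        hits = 0
        for seed in range(20):
            matrix, truth = simulate_haplotypes(
                HapSimConfig(n_carriers=20, g=200, seed=500 + seed)
            )
            core = core_haplotype(matrix)
            est = estimate_mrca(shared_lengths(matrix, core))
            hits += est.ci_low <= truth["g"] <= est.ci_high
        assert hits >= 16


class TestClusterSubhaplotypes:
    def _two_clade_matrix(self):
        """Recent within-clade MRCAs (sharing to +-1.5 cM) on an older shared
        core (+-0.3 cM); the clades carry complementary alleles between 0.3
        and 1.5 cM so their pairwise sharing never extends beyond the core."""
        rng = np.random.default_rng(17)
        n_markers = 41
        cm = (np.arange(n_markers) - 20) * 0.1  # -2 .. 2 cM, focal at 0
        ancestral = rng.integers(0, 2, size=n_markers).astype(np.int8)
        mid = (np.abs(cm) > 0.3) & (np.abs(cm) <= 1.5)
        far = np.abs(cm) > 1.5
        private_b = ancestral.copy()
        private_b[mid] = 1 - private_b[mid]
        rows = []
        for template in (ancestral, private_b):
            for _ in range(4):
                row = template.copy()
                row[far] = rng.integers(0, 2, size=int(far.sum())).astype(np.int8)
                rows.append(row)
        return toy_matrix(rows, cm=cm, focal=20)

    def test_two_clades_recovered_and_younger(self):
        matrix = self._two_clade_matrix()
        core = core_haplotype(matrix)
        cohort_est = estimate_mrca(shared_lengths(matrix, core))
        assignment, estimates = cluster_subhaplotypes(matrix, core)
        groups = set(assignment.group) - {"N"}
        assert len(groups) == 2
        for label in groups:
            est = estimates[label]
            if est is not None:
                assert est.g_hat <= cohort_est.g_hat

    def test_no_extension_gives_all_n(self):
        rng = np.random.default_rng(3)
        n_markers = 41
        cm = (np.arange(n_markers) - 20) * 0.1
        rows = rng.integers(0, 2, size=(6, n_markers)).astype(np.int8)
        rows[:, 18:23] = 1  # sharing only inside the core
        matrix = toy_matrix(rows, cm=cm, focal=20)
        core = core_haplotype(matrix)
        assignment, estimates = cluster_subhaplotypes(matrix, core, margin_cm=1.0)
        assert set(assignment.group) == {"N"}
        assert estimates == {}

    def test_single_clade(self):
        n_markers = 41
        cm = (np.arange(n_markers) - 20) * 0.1
        rows = np.ones((4, n_markers), dtype=np.int8)
        rng = np.random.default_rng(5)
        rows[:, :10] = rng.integers(0, 2, size=(4, 10))
        matrix = toy_matrix(rows, cm=cm, focal=20)
        core = core_haplotype(matrix)
        assignment, _ = cluster_subhaplotypes(matrix, core, margin_cm=0.5)
        assert len(set(assignment.group)) == 1


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "het,hom,n,decimals,expected",
        [
            (23, 1, 537, 3, 0.023),  # 25 alleles in 1,074 chromosomes
            (2, 1, 31, 2, 0.06),  # 4 alleles in 62 chromosomes
            (6, 0, 69, 2, 0.04),  # 6 alleles in 138 chromosomes
            (11, 0, 133, 2, 0.04),  # 11 alleles in 266 chromosomes
            (0, 0, 100, 3, 0.0),
        ],
    )
    def test_printed_cohort_values(self, het, hom, n, decimals, expected):
        assert allele_frequency(het, hom, n, decimals) == expected

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            allele_frequency(1, 0, 0)
        with pytest.raises(InvalidParameterError):
            allele_frequency(5, 6, 10)
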