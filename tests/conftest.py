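import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strexpand.simulate import (
    AAGGG_EXPANSION,
    COMPOUND_EXPANSION,
    REF_ALLELE,
    ReadSimConfig,
    simulate_reference,
    simulate_sample_reads,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(n: int, seed: int) -> str:
    """Deterministic random sequence; independent of the package's generators."""
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_sim():
    """A small reference with the (AAAAG)_11 locus at its centre, shared by tests."""
    config = ReadSimConfig(reference_length=6000, locus_offset=3000, seed=11)
    reference, locus = simulate_reference(config)
    return config, reference, locus


def sample_pairs(small_sim, genotype, seed, sample="s", coverage=None):
    config, reference, locus = small_sim
    if coverage is not None:
        from dataclasses import replace

        config = replace(config, coverage=coverage)
    return simulate_sample_reads(
        reference, locus, genotype, config, sample=sample,
        rng=np.random.default_rng(seed),
    )


@pytest.fixture(scope="session")
def hom_pairs(small_sim):
    return sample_pairs(small_sim, (AAGGG_EXPANSION, AAGGG_EXPANSION), seed=21, sample="hom")


@pytest.fixture(scope="session")
def het_pairs(small_sim):
    return sample_pairs(small_sim, (AAGGG_EXPANSION, REF_ALLELE), seed=22, sample="het")


@pytest.fixture(scope="session")
def ref_pairs(small_sim):
    return sample_pairs(small_sim, (REF_ALLELE, REF_ALLELE), seed=23, sample="ref")


@pytest.fixture(scope="session")
def compound_pairs(small_sim):
    return sample_pairs(
        small_sim, (AAGGG_EXPANSION, COMPOUND_EXPANSION), seed=24, sample="compound"
    )
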