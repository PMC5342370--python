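"""Shared fixtures: a small synthetic study reused across module tests."""
import pytest

from pirliver.simulate import SimConfig, generate_reference, simulate_counts


def small_sim_config(**overrides) -> SimConfig:
    base = dict(
        seed=7,
        n_contigs=2,
        contig_length=60_000,
        mito_length=8_000,
        n_genes=8,
        n_known_pirnas=30,
        n_decoy_sncrnas=10,
        n_planted_loci=8,
        n_samples_per_stage={"CN": 3, "pHCC": 3},
        n_transcripts=10,
        frac_low_expression=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_reference):
    return simulate_counts(small_config, small_reference.features)
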