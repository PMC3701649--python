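"""Shared fixtures: small simulated genomes reused across test modules."""

import pytest

import ltrtrace as lt


@pytest.fixture(scope="session")
def zero_age_sim():
    """Small genome with zero-age planted elements (identical LTRs, clean flanks)."""
    cfg = lt.SimulationConfig(
        seed=42,
        genome_length=300_000,
        n_intact=8,
        n_solo=2,
        n_truncated=3,
        age_distribution=("point", 0.0),
        family_birth_age=0.0,
    )
    return lt.simulate_genome(cfg)


@pytest.fixture(scope="session")
def aged_sim():
    """Genome under the default study conditions (ages 0.75-1.75 My)."""
    cfg = lt.SimulationConfig(
        seed=7, genome_length=600_000, n_intact=25, n_solo=2, n_truncated=6
    )
    return lt.simulate_genome(cfg)


@pytest.fixture(scope="session")
def sister_pair(aged_sim):
    """Sister genome at ~0.6% orthologous divergence retaining 83% of insertions."""
    return lt.simulate_sister(
        aged_sim.genome, aged_sim.truth, split_time=230_769, shared_fraction=0.83, seed=8
    )


@pytest.fixture(scope="session")
def identical_sister(zero_age_sim):
    """Sister genome with zero divergence and every insertion retained."""
    return lt.simulate_sister(
        zero_age_sim.genome, zero_age_sim.truth, split_time=0.0, shared_fraction=1.0, seed=9
    )
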