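import pytest

from txseq.synthetic_data import (
    SimulationConfig,
    as_aligned_fragments,
    simulate,
)

#: seed for the shared default-scale dataset; tests derive further seeds
DEFAULT_SEED = 7


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A fast, reduced-scale configuration for per-module tests."""
    defaults = dict(
        seed=seed,
        chrom_lengths=(220_000,),
        gene_count=12,
        fragments_per_sample=6_000,
        novel_tu_count=3,
        decoy_tu_count=0,
        de_tu_count=0,
        de_gene_count=2,
        skip_event_count=2,
        alt5_event_count=1,
        alt3_event_count=1,
        internal_priming_count=2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_sim():
    """The full default-scale two-sample dataset, simulated once."""
    config = SimulationConfig(seed=DEFAULT_SEED)
    bundle, reads = simulate(config)
    return config, bundle, reads


@pytest.fixture(scope="session")
def default_fragments(default_sim):
    config, bundle, reads = default_sim
    frags = []
    for sample in config.samples:
        frags.extend(as_aligned_fragments(reads, sample))
    return frags


@pytest.fixture(scope="session")
def small_sim():
    config = small_config(seed=3)
    bundle, reads = simulate(config)
    return config, bundle, reads
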