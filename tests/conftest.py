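import pytest

from quartet_phase.simulate import SimConfig, simulate_quartet


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free quartet on one 10 Mb chromosome (~11k sites)."""
    config = SimConfig(chromosome_lengths={"chr1": 10_000_000}, seed=41,
                       miscall_rate=0.0, missing_rate=0.0)
    return simulate_quartet(config)


@pytest.fixture(scope="session")
def noisy_sim():
    """Quartet with default miscall and missing rates (~23k sites)."""
    config = SimConfig(chromosome_lengths={"chr1": 12_000_000,
                                           "chr2": 8_000_000}, seed=42)
    return simulate_quartet(config)
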