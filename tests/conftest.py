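import pytest

from heteromir.synthetic import TriadSimConfig, simulate_triads


@pytest.fixture(scope="session")
def noise_free_triad():
    """Deterministic triad simulation (dispersion 0): counts, design, truth."""
    config = TriadSimConfig(n_mirnas=120, n_replicates=3, dispersion=0.0, seed=42)
    return simulate_triads(config)


@pytest.fixture(scope="session")
def noisy_triad():
    """Negative-binomial triad simulation at the default dispersion."""
    config = TriadSimConfig(n_mirnas=300, n_replicates=3, dispersion=0.05, seed=7)
    return simulate_triads(config)
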