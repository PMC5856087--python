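import pytest

from cardiofuse import synthgen


@pytest.fixture(scope="session")
def clean_pair():
    """10 noiseless, jitter-free paired cycles at 1000 Hz, 1 beat/s."""
    return synthgen.generate_paired(
        n_cycles=10, heart_rate=1.0, sampling_rate=1000.0,
        rr_jitter_sd=0.0, noise_sd=0.0, baseline_wander_amp=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def noisy_pair():
    """30 paired cycles with default noise, jitter and wander."""
    return synthgen.generate_paired(n_cycles=30, seed=11)
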