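import numpy as np
import pytest

import seqrsa as sq


@pytest.fixture(scope="session")
def subject_protocol():
    """One subject's full protocol (8 runs + behavioral sessions)."""
    return sq.build_full_protocol(1, seed=11)[0]


@pytest.fixture(scope="session")
def small_bank():
    return sq.sample_pattern_bank(40, seed=13)


@pytest.fixture(scope="session")
def normalized_tmaps(subject_protocol, small_bank):
    """Moderate-SNR simulated t-maps, run-normalized, for one subject."""
    amps = sq.CodingAmplitudes()
    tm = sq.simulate_tmaps(subject_protocol, small_bank, amps, seed=17)
    return sq.normalize_tmaps(tm)


@pytest.fixture(scope="session")
def all_matrices(subject_protocol, normalized_tmaps):
    return sq.build_all_matrices(normalized_tmaps, subject_protocol.sequences)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
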