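import numpy as np
import pytest

from csmux import guides


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_genome_50kb():
    """Uniform-random 50 kb genome with no planted motifs."""
    rng = np.random.default_rng(2024)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])


@pytest.fixture(scope="session")
def accepted_design():
    """First pre-sequence (seed 11) that survives promoter construction."""
    for p in guides.generate_presequences(400, 11):
        try:
            return guides.build_pair(p)
        except guides.RejectedDesign:
            continue
    raise RuntimeError("no accepted design in 400 candidates")
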