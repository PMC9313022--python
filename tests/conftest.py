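import numpy as np
import pytest

from splicescan.simulate import DoubletSpec, generate_doublet_gene, generate_score_table


@pytest.fixture(scope="session")
def planted_table():
    """Synthetic score table with the purine vocabulary planted high."""
    return generate_score_table(seed=0)


@pytest.fixture(scope="session")
def flat_table():
    """All-zero score table (no background noise, nothing planted)."""
    return generate_score_table(seed=0, planted={}, background_sd=0.0)


@pytest.fixture(scope="session")
def expanded_gene():
    return generate_doublet_gene(DoubletSpec(seed=1, expanded=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
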