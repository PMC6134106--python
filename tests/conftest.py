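import numpy as np
import pytest

from mitodyn.genome import Feature, Mitogenome, generate_mitogenome


@pytest.fixture(scope="session")
def default_genome():
    """Full-size synthetic mitogenome shared by read-only tests."""
    return generate_mitogenome(16211, seed=11)


@pytest.fixture(scope="session")
def small_genome():
    return generate_mitogenome(2000, seed=7, pad=100)


@pytest.fixture()
def coding_genome():
    """Tiny hand-built genome with one protein gene per strand, for
    brute-force translation checks."""
    rng = np.random.default_rng(5)
    length = 400
    seq = list(rng.choice(list("ACGT"), size=length))
    # heavy-strand gene at 51..140 (30 codons), light-strand gene at 201..290
    features = [
        Feature("GENEP", "protein", 51, 140, "+", 0),
        Feature("GENEM", "protein", 201, 290, "-", 0),
        Feature("CR", "noncoding", 301, 380, "+", 0),
    ]
    return Mitogenome("".join(seq), features, name="toy")
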