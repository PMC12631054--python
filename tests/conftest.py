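import pytest

from biasnet.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def s1_table():
    """Small seeded within-subjects table: 20 participants x 6 sources."""
    return generate(GeneratorConfig(design="S1", n_participants=20, seed=11))


@pytest.fixture(scope="session")
def s2_table():
    """Small seeded between-subjects table: 80 participants, one trial each."""
    return generate(GeneratorConfig(design="S2", n_participants=80, seed=11))
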