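import pytest

from gfmap import CompositionSpec, artificial_sequence, random_sequence

UNIFORM = (0.25, 0.25, 0.25, 0.25)


@pytest.fixture
def forty_mer():
    """The 40-bp worked-example circle (4 repeats of a 10-mer)."""
    return artificial_sequence()


@pytest.fixture
def random_seq():
    """A fixed seeded 300-bp uniform-composition sequence."""
    return random_sequence(CompositionSpec(fractions=UNIFORM, length=300, seed=7))


@pytest.fixture
def skewed_seq():
    """A fixed seeded GC-rich 250-bp sequence."""
    return random_sequence(
        CompositionSpec(fractions=(0.1, 0.4, 0.4, 0.1), length=250, seed=11)
    )
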