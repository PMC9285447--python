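import numpy as np
import pytest

from iconotrans import PhoneticFeatureTable, SyntheticConfig, generate


@pytest.fixture
def tiny_table() -> PhoneticFeatureTable:
    """Four phones over three ternary features."""
    return PhoneticFeatureTable(
        ["a", "b", "ab", "k"],
        np.array(
            [
                [1, 0, 0],
                [0, 1, 0],
                [1, 1, 0],
                [-1, 0, 1],
            ],
            dtype=float,
        ),
    )


@pytest.fixture(scope="session")
def small_lexicon():
    """A small six-language lexicon with planted iconic and class signal."""
    return generate(SyntheticConfig(n_concepts=40, seed=5))
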