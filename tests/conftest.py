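import numpy as np
import pytest

from phrasetag import (
    SyntheticLexiconSpec,
    generate_category_lexicon,
    simulate_null_itpc,
)


@pytest.fixture(scope="session")
def synth_lexicon():
    """Default category-clustered lexicon (300-d, 30 words per category)."""
    return generate_category_lexicon(SyntheticLexiconSpec(seed=0))


@pytest.fixture(scope="session")
def small_lexicon():
    """Cheap low-dimensional lexicon for stream-construction tests."""
    return generate_category_lexicon(SyntheticLexiconSpec(dim=40, n_per_category=30, seed=1))


@pytest.fixture(scope="session")
def null_24_32():
    """The study-scale random-phase null: K=24 trials, 32 electrodes."""
    return simulate_null_itpc(K=24, n_electrodes=32, n_rep=5000, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
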