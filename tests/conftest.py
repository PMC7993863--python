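import numpy as np
import pytest

import cannarel as cr


@pytest.fixture(scope="session")
def lex():
    return cr.fixture_lexicon(0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_corpus(lex):
    """120 separable synthetic records for quick training smokes."""
    return cr.generate_corpus(lex, cr.GeneratorConfig(n_records=120, seed=1))
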