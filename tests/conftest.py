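import pytest
from hypothesis import settings

from spictminer import default_lexicon, synthetic_lexicon

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lex():
    """The bundled English lexicon."""
    return default_lexicon()


@pytest.fixture(scope="session")
def synth_lex():
    """Bundled lexicon plus the synthetic segmentation mini-dictionary."""
    return synthetic_lexicon()
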