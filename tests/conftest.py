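import pytest

from cxrlabel import SynthConfig, generate_corpus, load_seed_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_seed_lexicon()


@pytest.fixture(scope="session")
def clean_corpus(lexicon):
    """A noise-free synthetic corpus: (descriptions, truth table)."""
    config = SynthConfig(n_reports=2000, misspell_rate=0.0, seed=11)
    return generate_corpus(config, lexicon)
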