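import pytest

from stenoscan import compile_rules, external_config, generate_corpus, internal_config


@pytest.fixture(scope="session")
def matcher():
    return compile_rules()


@pytest.fixture(scope="session")
def clean_internal_corpus():
    """Noise-free, in-lexicon internal-dialect corpus (small)."""
    return generate_corpus(
        internal_config(200, noise_rate=0.0, oov_synonym_rate=0.0, seed=101)
    )


@pytest.fixture(scope="session")
def clean_external_corpus():
    """Noise-free, in-lexicon external-dialect corpus (small)."""
    return generate_corpus(
        external_config(200, noise_rate=0.0, oov_synonym_rate=0.0, seed=102)
    )
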