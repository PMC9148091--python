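import numpy as np
import pytest

from radsections.synthetic import GeneratorConfig, generate_corpus
from radsections.wordpiece import train_wordpiece


@pytest.fixture(scope="session")
def small_corpus():
    """120 synthetic gold records shared by the read-only tests."""
    return generate_corpus(GeneratorConfig(n_reports=120, seed=7))


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    sentences = [s.text for rec in small_corpus for s in rec.report.sentences]
    return train_wordpiece(sentences, vocab_size=2000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
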