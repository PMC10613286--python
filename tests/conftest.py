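import numpy as np
import pytest

from glottolearn.corpus_io import ParallelCorpus
from glottolearn.synthetic_world import WorldConfig, generate_world, make_source


@pytest.fixture(scope="session")
def small_world():
    """A 12-language world shared by read-only tests."""
    return generate_world(WorldConfig(n_languages=12, n_verses=200, seed=42))


@pytest.fixture(scope="session")
def single_language_corpus():
    """1000 verses of one moderately hard Markov language, 10 books."""
    rng = np.random.default_rng(9)
    src = make_source(vocab=40, order=1, entropy_bits=2.3)
    n_verses = 500
    lengths = np.maximum(1, rng.poisson(12, n_verses))
    stream = src.sample(int(lengths.sum()), rng)
    per_book = n_verses // 10
    verses, pos = {}, 0
    for v in range(n_verses):
        key = (f"b{v // per_book + 1:02d}", 1, v % per_book + 1)
        chunk = stream[pos : pos + lengths[v]]
        pos += lengths[v]
        verses[key] = {"LX": " ".join(f"w{c:03d}" for c in chunk)}
    return ParallelCorpus(["LX"], verses), src
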