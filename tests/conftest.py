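import numpy as np
import pytest

from pepgen import corpus as corpus_mod
from pepgen import generator
from pepgen.corpus import CANONICAL, Corpus, Peptide


def make_distinct_start_corpus(n=10, length=30, seed=3):
    """Sequences with pairwise-distinct first residues (so that greedy
    completion primed with the first residue is well-defined)."""
    rng = np.random.default_rng(seed)
    alphabet = list(CANONICAL)
    peps = []
    for i in range(n):
        tail = "".join(rng.choice(alphabet, size=length - 1))
        peps.append(Peptide(f"p{i}", alphabet[i] + tail, "training"))
    return Corpus(peps)


@pytest.fixture(scope="session")
def memorization_corpus():
    return make_distinct_start_corpus()


@pytest.fixture(scope="session")
def memorized_model(memorization_corpus):
    """2x64-unit model trained to memorize a 10-sequence corpus (shared
    across tests because training takes a few seconds)."""
    batch = corpus_mod.encode(memorization_corpus)
    cfg = generator.ModelConfig(
        layers=2, units_per_layer=64, dropout_per_layer=(0.0, 0.0),
        epochs=500, seed=7,
    )
    state, trace = generator.train(batch, cfg)
    return state, trace
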