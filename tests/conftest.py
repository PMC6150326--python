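import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glypre as g
from glypre.synthetic_data import (
    MotifSpec,
    SyntheticConfig,
    generate_corpus,
    generate_aaindex_fixture,
    worked_micro_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def micro():
    """Six tiny proteins with four positive lysines; hand-checkable."""
    return worked_micro_dataset()


@pytest.fixture(scope="session")
def aaindex_file(tmp_path_factory):
    """A 20-index synthetic AAindex1 file (one NA cell) plus its accessions."""
    path = tmp_path_factory.mktemp("aaindex") / "aaindex1.txt"
    text, accessions = generate_aaindex_fixture(n_indices=20, seed=11, n_na=1)
    path.write_text(text)
    return path, accessions


@pytest.fixture(scope="session")
def aaindex_table(aaindex_file):
    path, accessions = aaindex_file
    return g.read_aaindex1(path, accessions, zscore=True)


@pytest.fixture(scope="session")
def tiny_setup(aaindex_table):
    """A small planted-signal corpus for fast pipeline tests (n = 72)."""
    cfg = SyntheticConfig(n_proteins=12, positives_per_protein=2,
                          length_range=(200, 260), seed=3)
    corpus = generate_corpus(cfg)
    dataset = g.build_dataset(corpus.proteins, corpus.annotations,
                              window_size=31, neg_per_pos=2.0, seed=3)
    encoded = g.prepare_corpus(corpus.proteins, dataset, corpus.profiles,
                               aaindex_table, g.EncoderConfig())
    return corpus, dataset, encoded


@pytest.fixture(scope="session")
def planted_setup(aaindex_table):
    """The study-scale planted corpus: 210 positives, 1:2 ratio (n = 630)."""
    corpus = generate_corpus(SyntheticConfig(seed=11))
    dataset = g.build_dataset(corpus.proteins, corpus.annotations,
                              window_size=31, neg_per_pos=2.0, seed=11)
    encoded = g.prepare_corpus(corpus.proteins, dataset, corpus.profiles,
                               aaindex_table, g.EncoderConfig())
    return corpus, dataset, encoded
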