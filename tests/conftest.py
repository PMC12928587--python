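import numpy as np
import pytest

from plmsubnet import (
    DomainRecord,
    SyntheticSpec,
    Vocabulary,
    build_toy_model,
    generate_corpus,
)


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary()


@pytest.fixture(scope="session")
def tiny_model(vocab):
    """Small but real transformer: 2 blocks, width 16, 4 heads."""
    return build_toy_model(vocab, depth=2, width=16, n_heads=4, max_len=128, seed=7)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Short corpus for fast functional tests (not the default study conditions)."""
    spec = SyntheticSpec(n_per_class=12, length_range=(64, 72), seed=11)
    return generate_corpus(spec)


@pytest.fixture()
def labelled_records():
    return [
        DomainRecord("a", "ACDEFGHIKL", cath_label="1.10.8.10", ss3="HHHHHLLLEE"),
        DomainRecord("b", "MNPQRSTVWY", cath_label="2.40.50.140", ss3="EEEELLLLHH"),
        DomainRecord("c", "ACACACACAC", cath_label="1.20.5.10", ss3="LLHHHHEELL"),
        DomainRecord("d", "WYWYWYWYWY", cath_label="3.40.50.720", ss3="HEELLLLLHH"),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
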