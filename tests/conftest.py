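import numpy as np
import pytest

import docrex as dx


@pytest.fixture(scope="session")
def figure1_doc():
    return dx.figure1_fixture()


@pytest.fixture(scope="session")
def small_corpus():
    """A structurally varied synthetic corpus (multiple concepts per doc)."""
    cfg = dx.SyntheticConfig(
        n_docs=30,
        chemicals_per_doc=(1, 3),
        diseases_per_doc=(1, 3),
        sentences_per_doc=(4, 10),
        mentions_per_concept=(1, 3),
        seed=42,
    )
    return dx.generate_corpus(cfg)


@pytest.fixture(scope="session")
def tiny_model():
    """A random tiny encoder (both the config and the parameter dict)."""
    cfg = dx.ModelConfig(n_stacks=2, n_heads=2, d_model=8, n_max=6,
                         vocab_size=11, n_classes=3, dropout=0.0)
    params = dx.init_params(cfg, np.random.default_rng(7))
    # widen the init so attention is non-degenerate
    params = {k: v * 10 if v.ndim > 1 else v for k, v in params.items()}
    return cfg, params


@pytest.fixture(scope="session")
def cued_split():
    """A train/held-out pair of replacement-pretreated synthetic instance sets
    with a fully emitted lexical cue (the learnability study conditions)."""
    train_docs = dx.generate_corpus(dx.SyntheticConfig(n_docs=340, seed=11))
    train = dx.build_corpus_instances(train_docs)[:500]
    held_docs = dx.generate_corpus(dx.SyntheticConfig(n_docs=120, seed=999))
    held = dx.build_corpus_instances(held_docs)
    return train, held
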