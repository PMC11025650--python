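"""Shared fixtures: the micro-world, a training corpus, and one trained
model of each kind (session-scoped; training is the expensive step)."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sgn400 import (LMConfig, SGConfig, default_microworld,
                    filter_training_sentences, sample_corpus, train_lm,
                    train_sg)


@pytest.fixture(scope="session")
def world():
    return default_microworld()


@pytest.fixture(scope="session")
def train_corpus(world):
    return filter_training_sentences(sample_corpus(world, 400, seed=7))


@pytest.fixture(scope="session")
def trained_sg(train_corpus):
    model, log = train_sg(train_corpus, SGConfig(seed=7, max_epochs=40))
    model._train_log = log
    return model


@pytest.fixture(scope="session")
def trained_lm(train_corpus):
    model, log = train_lm(train_corpus, LMConfig(seed=7, max_epochs=15))
    model._train_log = log
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
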