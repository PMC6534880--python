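"""Shared fixtures.  Heavy artifacts (toy corpus, pre-trained generator,
RF predictor) are session-scoped so the pre-training cost is paid once."""

from __future__ import annotations

import numpy as np
import pytest

from smilesrl.fixtures import (
    FixtureConfig,
    generate_activity_set,
    generate_corpus,
)
from smilesrl.generator import GeneratorModel, pretrain
from smilesrl.qsar import curate_activity_dataset, train_predictor
from smilesrl.vocab import Vocabulary, build_vocabulary

# Desk-scale generator architecture used across the suite; the paper-scale
# defaults (128/512/3) are exercised only for shape checks.
TOY_NET = dict(embed_dim=32, hidden_dim=64, n_layers=1)
TOY_TRAIN = dict(batch_size=128, lr=2e-3)


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return generate_corpus(FixtureConfig(n_molecules=2000, seed=1))


@pytest.fixture(scope="session")
def toy_vocab(toy_corpus) -> Vocabulary:
    return build_vocabulary(toy_corpus)


@pytest.fixture(scope="session")
def activity_dataset():
    cfg = FixtureConfig(n_molecules=600, seed=7, label_noise=0.05)
    return curate_activity_dataset(generate_activity_set(cfg))


@pytest.fixture(scope="session")
def rf_predictor(activity_dataset):
    return train_predictor(activity_dataset, "RF", seed=0)


@pytest.fixture(scope="session")
def pretrained_run(toy_corpus, toy_vocab):
    """(model, log) of the shared 50-epoch seed-0 pre-training run."""
    return pretrain(toy_corpus, toy_vocab, epochs=50, seed=0,
                    valid_sample_size=0, **TOY_NET, **TOY_TRAIN)


@pytest.fixture(scope="session")
def pretrained_model(pretrained_run) -> GeneratorModel:
    return pretrained_run[0]


@pytest.fixture
def tiny_model() -> GeneratorModel:
    """A 5-token random-weight generator for cheap mechanical tests."""
    vocab = Vocabulary.from_symbols(["GO", "EOS", "C", "O", "c"])
    return GeneratorModel(vocab, embed_dim=4, hidden_dim=6, n_layers=2,
                          max_steps=20, seed=42)


class StubEstimator:
    """predict_proba driven by the presence of one fingerprint bit."""

    def __init__(self, bit: int, p_on: float = 0.9, p_off: float = 0.1):
        self.bit = bit
        self.p_on = p_on
        self.p_off = p_off

    def predict_proba(self, X):
        p1 = np.where(X[:, self.bit] > 0, self.p_on, self.p_off)
        return np.column_stack([1.0 - p1, p1])


class ConstantEstimator:
    def __init__(self, p: float):
        self.p = p

    def predict_proba(self, X):
        p1 = np.full(X.shape[0], self.p)
        return np.column_stack([1.0 - p1, p1])


@pytest.fixture
def stub_estimator_cls():
    return StubEstimator


@pytest.fixture
def constant_estimator_cls():
    return ConstantEstimator
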