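"""Canned reproducible experiments used by the examples and scripts.

The main entry point is :func:`end_to_end_recovery`: generate a synthetic
lexicon and corpus, train the reduced tagger on one CPU, and measure strict
span-level precision/recall/F1 on held-out sentences.  The reduced setup
(50-dim word embeddings, 50 LSTM hidden units, 15 epochs, 1000 train / 200
dev sentences, 30% out-of-lexicon entity mentions) keeps a full run in the
minutes range while exercising every component: char-CNN morphology is the
only route to the OOV mentions, the gazetteer feature carries the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .corpus import Corpus
from .evaluation import EvalReport, evaluate_corpus
from .model import NerModel
from .synthetic import GenerationInfo, SynthConfig, generate_corpus, generate_lexicon
from .training import TrainHistory, train

__all__ = ["end_to_end_recovery", "EndToEndResult"]


@dataclass
class EndToEndResult:
    report: EvalReport
    history: TrainHistory
    model: NerModel
    train_set: Corpus
    dev_set: Corpus
    info: GenerationInfo


def make_split(
    seed: int, *, n_train: int = 1000, n_dev: int = 200, oov_entity_rate: float = 0.3
) -> tuple[Corpus, Corpus, GenerationInfo]:
    """Synthetic train/dev split drawn from one lexicon."""
    cfg = SynthConfig(
        n_sentences=n_train + n_dev, oov_entity_rate=oov_entity_rate, seed=seed
    )
    rng = np.random.default_rng(seed)
    lex, names = generate_lexicon(cfg, rng)
    info = GenerationInfo()
    corpus = generate_corpus(cfg, lex, rng, names=names, info=info)
    train_set = Corpus(corpus.sentences[:n_train], corpus.tag_alphabet)
    dev_set = Corpus(corpus.sentences[n_train:], corpus.tag_alphabet)
    return train_set, dev_set, info


def end_to_end_recovery(
    seed: int = 1,
    *,
    n_train: int = 1000,
    n_dev: int = 200,
    oov_entity_rate: float = 0.3,
    max_epochs: int = 15,
) -> EndToEndResult:
    """Train the reduced model on synthetic data; evaluate held-out span F1."""
    train_set, dev_set, info = make_split(
        seed, n_train=n_train, n_dev=n_dev, oov_entity_rate=oov_entity_rate
    )
    config = ModelConfig(
        word_dim=50, lstm_hidden=50, max_epochs=max_epochs, batch_size=16, seed=seed
    )
    model, history = train(train_set, dev_set, config, np.random.default_rng(seed))
    report = evaluate_corpus(dev_set, model.predict_corpus(dev_set))
    return EndToEndResult(report, history, model, train_set, dev_set, info)
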