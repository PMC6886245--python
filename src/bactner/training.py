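"""Mini-batch training: Adam, dropout, lr decay, early stopping.

The loop optimizes the mean per-sentence CRF negative log-likelihood by
backpropagation, multiplies the learning rate by ``config.decay`` after
each epoch, evaluates span-level F1 on the validation set every epoch, and
stops once ``patience`` consecutive evaluations fail to beat the best F1 by
more than ``tol``.  The returned model carries the best-epoch parameters.
All randomness (shuffling, dropout) flows from one seeded generator, so a
fixed seed reproduces the run exactly (single-threaded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .corpus import Corpus, Sentence
from .evaluation import evaluate_corpus
from .model import NerModel
from .nn import Param

__all__ = ["TrainHistory", "EpochRecord", "make_batches", "train", "early_stop", "Adam"]

logger = logging.getLogger(__name__)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    dev_f1: float
    lr: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_f1: float = -1.0
    stopped_early: bool = False

    def append(self, rec: EpochRecord, tol: float) -> None:
        self.records.append(rec)
        if rec.dev_f1 > self.best_f1 + tol or self.best_epoch < 0:
            self.best_f1 = rec.dev_f1
            self.best_epoch = rec.epoch


@dataclass
class Batch:
    """A padded mini-batch: sentences plus a (B, L) validity mask.

    ``lengths`` gives each sentence's true token count; positions with
    ``mask == False`` are padding and are excluded from loss, partition and
    Viterbi (the model only ever sees the unpadded token range).
    """

    sentences: list[Sentence]
    lengths: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return len(self.sentences)


def make_batches(
    corpus: Corpus, batch_size: int, rng: np.random.Generator
) -> list[Batch]:
    """Shuffle the corpus (seed-deterministic) and slice into padded batches."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if len(corpus) == 0:
        raise ValueError("cannot batch an empty corpus")
    order = rng.permutation(len(corpus))
    sentences = [corpus.sentences[i] for i in order]
    batches = []
    for i in range(0, len(sentences), batch_size):
        chunk = sentences[i:i + batch_size]
        lengths = np.array([len(s) for s in chunk])
        L = int(lengths.max())
        mask = np.arange(L)[None, :] < lengths[:, None]
        batches.append(Batch(chunk, lengths, mask))
    return batches


def batch_nll(
    model: NerModel, batch: Batch, *, train_mode: bool = False,
    rng: np.random.Generator | None = None, accumulate_grads: bool = False,
) -> float:
    """Mean per-sentence NLL over the batch's unmasked positions."""
    scale = 1.0 / len(batch)
    total = 0.0
    for sent in batch.sentences:
        total += model.sentence_nll(
            sent, train_mode=train_mode, rng=rng,
            accumulate_grads=accumulate_grads, grad_scale=scale,
        )
    return total * scale


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: list[Param], config: ModelConfig) -> None:
        self.params = params
        self.lr = config.lr
        self.b1 = config.adam_beta1
        self.b2 = config.adam_beta2
        self.eps = config.adam_eps
        self.clip = config.grad_clip
        self.t = 0
        self._m = {p.name: np.zeros_like(p.value) for p in params}
        self._v = {p.name: np.zeros_like(p.value) for p in params}

    def step(self) -> None:
        if self.clip > 0:
            norm = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
            if norm > self.clip:
                scale = self.clip / norm
                for p in self.params:
                    p.grad *= scale
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p in self.params:
            m = self._m[p.name]
            v = self._v[p.name]
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def early_stop(history: TrainHistory, patience: int, tol: float) -> bool:
    """True iff the last *patience* evaluations all failed to beat the best
    F1 seen before them by more than *tol*."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    recs = history.records
    if len(recs) <= patience:
        return False
    recent = recs[-patience:]
    best_before = max(r.dev_f1 for r in recs[:-patience])
    return all(r.dev_f1 <= best_before + tol for r in recent)


def train(
    train_set: Corpus,
    dev_set: Corpus,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
    *,
    pretrained_words: dict[str, np.ndarray] | None = None,
    model: NerModel | None = None,
) -> tuple[NerModel, TrainHistory]:
    """Train a tagger; returns (model with best-epoch parameters, history)."""
    if set(dev_set.tag_alphabet) - set(train_set.tag_alphabet):
        raise ValueError("dev-set tags not covered by the training tag alphabet")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if model is None:
        model = NerModel.from_corpus(
            train_set, config, rng, pretrained_words=pretrained_words
        )
    optimizer = Adam(model.params(), config)
    history = TrainHistory()
    best_state = model.state_dict()
    lr = config.lr
    for epoch in range(1, config.max_epochs + 1):
        optimizer.lr = lr
        epoch_loss = 0.0
        batches = make_batches(train_set, config.batch_size, rng)
        for batch in batches:
            model.zero_grads()
            loss = batch_nll(
                model, batch, train_mode=True, rng=rng, accumulate_grads=True
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            optimizer.step()
            model.crf.apply_mask()
            epoch_loss += loss * len(batch)
        epoch_loss /= len(train_set)
        dev_f1 = evaluate_corpus(dev_set, model.predict_corpus(dev_set)).f1
        history.append(EpochRecord(epoch, epoch_loss, dev_f1, lr), config.tol)
        if history.best_epoch == epoch:
            best_state = model.state_dict()
        logger.info(
            "epoch %d: loss %.4f dev-F1 %.3f lr %.2e", epoch, epoch_loss, dev_f1, lr
        )
        if early_stop(history, config.patience, config.tol):
            history.stopped_early = True
            logger.info("early stopping at epoch %d (best epoch %d)",
                        epoch, history.best_epoch)
            break
        lr *= config.decay
    model.load_state_dict(best_state)
    return model, history
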