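"""The hybrid tagger: embedding layer, BiLSTM encoder, CRF decoder.

Per token, four embeddings are concatenated — word (case-folded lookup with
a trainable UNK row), character-level CNN output, POS and dictionary-feature
lookups — and fed to a bidirectional LSTM; an affine projection maps each
position's encoder state to per-tag emission scores, which a linear-chain
CRF decodes.  Dropout (train mode only) is applied to the concatenated
embedding and to the encoder output.

The model owns all parameters and exposes per-sentence ``forward_pass`` /
``loss_and_grads`` / ``predict``, plus checkpoint save/load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .config import ModelConfig
from .corpus import Corpus, Sentence
from .crf import CRFParams, crf_nll_grad, viterbi_decode
from .nn import (
    Affine,
    CharCNNParams,
    Dropout,
    EmbeddingTable,
    LSTMParams,
    Param,
    char_cnn_encode,
)

__all__ = ["NerModel", "emission_scores", "load_word2vec_text"]


def emission_scores(encoded: np.ndarray, projection: Affine) -> np.ndarray:
    """Project encoder states (n x 2*hidden) to per-tag scores P (n x m)."""
    return projection.forward(encoded)

CHECKPOINT_VERSION = 1


def load_word2vec_text(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Read a word2vec text-format embedding file.

    Format: a header line ``<count> <dim>`` followed by one line per token:
    the token then ``dim`` whitespace-separated floats.  Returns the
    token->vector map and the dimension.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected header '<count> <dim>'")
        count, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                raise ValueError(f"{path}:{lineno}: expected {dim + 1} fields")
            vectors[parts[0]] = np.asarray(parts[1:dim + 1], dtype=np.float64)
    if len(vectors) != count:
        raise ValueError(f"{path}: header declared {count} vectors, found {len(vectors)}")
    return vectors, dim


def _feature_alphabet(corpus: Corpus, attr: str) -> list[str]:
    seen: dict[str, None] = {}
    for sent in corpus:
        for tok in sent:
            seen.setdefault(getattr(tok, attr), None)
    return list(seen)


class NerModel:
    """BiLSTM-CRF tagger with word / char-CNN / POS / dict embeddings."""

    def __init__(
        self,
        config: ModelConfig,
        tag_alphabet: tuple[str, ...],
        word_vocab: list[str],
        char_vocab: list[str],
        pos_vocab: list[str],
        dict_vocab: list[str],
        rng: np.random.Generator,
    ) -> None:
        self.config = config
        self.tag_alphabet = tuple(tag_alphabet)
        self.tag_index = {t: i for i, t in enumerate(self.tag_alphabet)}
        c = config
        self.word_emb = EmbeddingTable(
            word_vocab, c.word_dim, rng, name="word_emb", case_fold=True
        )
        self.char_cnn = CharCNNParams.create(
            char_vocab, c.char_dim, c.filter_size, c.filter_deep, rng
        )
        self.pos_emb = EmbeddingTable(pos_vocab, c.pos_dim, rng, name="pos_emb")
        self.dict_emb = EmbeddingTable(dict_vocab, c.dict_dim, rng, name="dict_emb")
        self.fwd = LSTMParams.create(c.input_dim, c.lstm_hidden, rng, prefix="lstm_fwd")
        self.bwd = LSTMParams.create(c.input_dim, c.lstm_hidden, rng, prefix="lstm_bwd")
        self.proj = Affine(2 * c.lstm_hidden, len(self.tag_alphabet), rng, name="proj")
        self.crf = CRFParams.create(self.tag_alphabet)
        self.crf_T = Param("crf_T", self.crf.T)
        self.crf.T = self.crf_T.value
        self.crf.apply_mask()
        self.emb_dropout = Dropout(c.dropout)
        self.out_dropout = Dropout(c.dropout)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_corpus(
        cls,
        corpus: Corpus,
        config: ModelConfig,
        rng: np.random.Generator,
        *,
        pretrained_words: dict[str, np.ndarray] | None = None,
    ) -> "NerModel":
        """Build vocabularies from a training corpus and initialize parameters."""
        words: dict[str, None] = {}
        chars: dict[str, None] = {}
        for sent in corpus:
            for tok in sent:
                words.setdefault(tok.surface.casefold(), None)
                for ch in tok.surface:
                    chars.setdefault(ch, None)
        model = cls(
            config,
            tuple(corpus.tag_alphabet),
            list(words),
            list(chars),
            _feature_alphabet(corpus, "pos"),
            _feature_alphabet(corpus, "dict_feat"),
            rng,
        )
        if pretrained_words is not None:
            for tok, vec in pretrained_words.items():
                if len(vec) != config.word_dim:
                    raise ValueError("pretrained vector dimension mismatch")
                model.word_emb.set_vector(tok, vec)
        return model

    def params(self) -> list[Param]:
        ps = [self.word_emb.param, self.char_cnn.char_table.param,
              self.char_cnn.W1, self.char_cnn.b1,
              self.pos_emb.param, self.dict_emb.param]
        ps += self.fwd.params() + self.bwd.params()
        ps += self.proj.params()
        ps.append(self.crf_T)
        if self.config.freeze_word_embeddings:
            ps.remove(self.word_emb.param)
        return ps

    def zero_grads(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------

    def _embed(self, sentence: Sentence):
        surfaces = sentence.surfaces
        w_vecs, w_idx = self.word_emb.lookup(surfaces)
        c_vecs = []
        c_caches = []
        for s in surfaces:
            vec, cache = char_cnn_encode(s, self.char_cnn, with_cache=True)
            c_vecs.append(vec)
            c_caches.append(cache)
        c_vecs = np.stack(c_vecs)
        p_vecs, p_idx = self.pos_emb.lookup(sentence.pos_tags)
        d_vecs, d_idx = self.dict_emb.lookup(sentence.dict_feats)
        x = np.concatenate([w_vecs, c_vecs, p_vecs, d_vecs], axis=1)
        return x, (w_idx, c_caches, p_idx, d_idx)

    def forward_pass(
        self,
        sentence: Sentence,
        *,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
        with_cache: bool = False,
    ):
        """Emission matrix P (n x m) for one sentence.

        In train mode dropout is applied (requires *rng*); inference is
        deterministic.
        """
        if len(sentence) == 0:
            raise ValueError("cannot encode an empty sentence")
        if train_mode and rng is None:
            raise ValueError("train_mode requires an rng for dropout")
        x, emb_cache = self._embed(sentence)
        x_drop, emb_mask = self.emb_dropout.forward(x, rng, train_mode)
        H, lstm_cache = nn.bilstm_encode(x_drop, self.fwd, self.bwd, with_cache=True)
        H_drop, out_mask = self.out_dropout.forward(H, rng, train_mode)
        P = self.proj.forward(H_drop)
        if not with_cache:
            return P
        cache = (x, emb_cache, emb_mask, x_drop, lstm_cache, H, out_mask, H_drop)
        return P, cache

    def backward(self, sentence: Sentence, cache, dP: np.ndarray) -> None:
        """Backprop emission-score gradients into all parameter grads."""
        (x, emb_cache, emb_mask, x_drop, lstm_cache, H, out_mask, H_drop) = cache
        dH_drop = self.proj.backward(H_drop, dP)
        dH = Dropout.backward(dH_drop, out_mask)
        dx_drop = nn.bilstm_backward(dH, lstm_cache, self.fwd, self.bwd)
        dx = Dropout.backward(dx_drop, emb_mask)
        c = self.config
        w_idx, c_caches, p_idx, d_idx = emb_cache
        ofs = 0
        d_word = dx[:, ofs:ofs + c.word_dim]; ofs += c.word_dim
        d_char = dx[:, ofs:ofs + c.filter_deep]; ofs += c.filter_deep
        d_pos = dx[:, ofs:ofs + c.pos_dim]; ofs += c.pos_dim
        d_dict = dx[:, ofs:ofs + c.dict_dim]
        if not c.freeze_word_embeddings:
            self.word_emb.backward(w_idx, d_word)
        for t, ch_cache in enumerate(c_caches):
            nn.char_cnn_backward(d_char[t], ch_cache, self.char_cnn)
        self.pos_emb.backward(p_idx, d_pos)
        self.dict_emb.backward(d_idx, d_dict)

    def sentence_nll(
        self, sentence: Sentence, *, train_mode: bool = False,
        rng: np.random.Generator | None = None, accumulate_grads: bool = False,
        grad_scale: float = 1.0,
    ) -> float:
        """CRF negative log-likelihood of the gold tags for one sentence."""
        y_gold = [self.tag_index[t] for t in sentence.gold_tags]
        P, cache = self.forward_pass(
            sentence, train_mode=train_mode, rng=rng, with_cache=True
        )
        nll, dP, dT = crf_nll_grad(P, self.crf, y_gold)
        if accumulate_grads:
            self.crf_T.grad += grad_scale * dT
            self.backward(sentence, cache, grad_scale * dP)
        return float(nll)

    def predict(self, sentence: Sentence) -> list[str]:
        """Viterbi-decode the most probable IOB2 tag sequence."""
        if len(sentence) == 0:
            return []
        P = self.forward_pass(sentence)
        path, _score = viterbi_decode(P, self.crf)
        return [self.tag_alphabet[i] for i in path]

    def predict_corpus(self, corpus: Corpus) -> list[list[str]]:
        return [self.predict(s) for s in corpus]

    # -- state --------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self._all_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self._all_params():
            p.value[...] = state[p.name]
        self.crf.apply_mask()

    def _all_params(self) -> list[Param]:
        ps = [self.word_emb.param, self.char_cnn.char_table.param,
              self.char_cnn.W1, self.char_cnn.b1,
              self.pos_emb.param, self.dict_emb.param]
        ps += self.fwd.params() + self.bwd.params()
        ps += self.proj.params()
        ps.append(self.crf_T)
        return ps

    def save(self, path: str | Path) -> None:
        """Write a checkpoint: .npz parameter archive + JSON sidecar with
        vocabularies, tag alphabet and config."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "tag_alphabet": list(self.tag_alphabet),
            "word_vocab": list(self.word_emb.vocab),
            "char_vocab": list(self.char_cnn.char_table.vocab),
            "pos_vocab": list(self.pos_emb.vocab),
            "dict_vocab": list(self.dict_emb.vocab),
        }
        path.with_suffix(".json").write_text(
            json.dumps(meta, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "NerModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")

        def strip(vocab: list[str]) -> list[str]:
            return [t for t in vocab if t not in (nn.UNK, nn.PAD)]

        model = cls(
            ModelConfig.from_dict(meta["config"]),
            tuple(meta["tag_alphabet"]),
            strip(meta["word_vocab"]),
            strip(meta["char_vocab"]),
            strip(meta["pos_vocab"]),
            strip(meta["dict_vocab"]),
            np.random.default_rng(0),
        )
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
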