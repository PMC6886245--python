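"""Neural building blocks with explicit forward/backward passes.

Everything here is plain numpy with hand-written gradients: embedding
lookup tables, the character-level CNN (convolution over character
embeddings followed by max-pooling), the LSTM cell and bidirectional
encoder, an affine projection, and inverted dropout.  Gradients accumulate
into each :class:`Param`'s ``.grad`` buffer; the training loop zeroes and
consumes them.

Initialization conventions: embedding tables are uniform on
``[-sqrt(3/dim), +sqrt(3/dim)]``; convolution and fully-connected weights
use Glorot uniform; biases start at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Param",
    "EmbeddingTable",
    "init_uniform",
    "glorot_uniform",
    "CharCNNParams",
    "char_cnn_encode",
    "LSTMParams",
    "lstm_step",
    "lstm_forward",
    "bilstm_encode",
    "Affine",
    "Dropout",
    "UNK",
    "PAD",
]

UNK = "<unk>"
PAD = "<pad>"


class Param:
    """A named trainable array with a gradient buffer."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray) -> None:
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape})"


def init_uniform(vocab_size: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform embedding initialization on ``[-sqrt(3/dim), +sqrt(3/dim)]``."""
    if dim <= 0:
        raise ValueError("dim must be positive")
    bound = math.sqrt(3.0 / dim)
    return rng.uniform(-bound, bound, size=(vocab_size, dim))


def glorot_uniform(fan_out: int, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_out, fan_in))


class EmbeddingTable:
    """token -> row lookup with UNK (and PAD) rows and scatter-add backward."""

    def __init__(
        self,
        tokens: Iterable[str],
        dim: int,
        rng: np.random.Generator,
        *,
        name: str = "emb",
        add_pad: bool = False,
        case_fold: bool = False,
    ) -> None:
        self.case_fold = case_fold
        specials = [UNK] + ([PAD] if add_pad else [])
        vocab: dict[str, int] = {}
        for tok in specials:
            vocab[tok] = len(vocab)
        for tok in tokens:
            tok = tok.casefold() if case_fold else tok
            if tok not in vocab:
                vocab[tok] = len(vocab)
        self.vocab = vocab
        self.dim = dim
        self.param = Param(name, init_uniform(len(vocab), dim, rng))
        if add_pad:
            self.param.value[vocab[PAD]] = 0.0  # pad embedding fixed at zero
        self.pad_index = vocab.get(PAD)

    @property
    def matrix(self) -> np.ndarray:
        return self.param.value

    def index(self, token: str) -> int:
        if self.case_fold:
            token = token.casefold()
        return self.vocab.get(token, self.vocab[UNK])

    def lookup(self, tokens: list[str]) -> tuple[np.ndarray, list[int]]:
        idx = [self.index(t) for t in tokens]
        return self.param.value[idx], idx

    def backward(self, idx: list[int], grad: np.ndarray) -> None:
        np.add.at(self.param.grad, idx, grad)
        if self.pad_index is not None:
            self.param.grad[self.pad_index] = 0.0

    def set_vector(self, token: str, vec: np.ndarray) -> None:
        if self.case_fold:
            token = token.casefold()
        if token in self.vocab:
            self.param.value[self.vocab[token]] = vec


# ---------------------------------------------------------------------------
# Character CNN
# ---------------------------------------------------------------------------

@dataclass
class CharCNNParams:
    """Character table + one convolution (N kernels of width k) + max-pool."""

    char_table: EmbeddingTable
    k: int
    N: int
    W1: Param  # (N, k * char_dim)
    b1: Param  # (N,)

    @classmethod
    def create(
        cls, chars: Iterable[str], char_dim: int, k: int, N: int,
        rng: np.random.Generator,
    ) -> "CharCNNParams":
        if k % 2 != 1:
            raise ValueError("convolution width k must be odd")
        table = EmbeddingTable(chars, char_dim, rng, name="char_emb", add_pad=True)
        W1 = Param("char_W1", glorot_uniform(N, k * char_dim, rng))
        b1 = Param("char_b1", np.zeros(N))
        return cls(table, k, N, W1, b1)


def char_cnn_encode(
    word: str, params: CharCNNParams, *, with_cache: bool = False
):
    """Encode one word into an N-vector: windowed convolution + relu + max-pool.

    Same-padding: the window at character i covers ``k`` characters centred
    on i, with the dedicated pad symbol beyond the boundaries.  The empty
    word maps to the zero vector.
    """
    N = params.N
    if len(word) == 0:
        out = np.zeros(N)
        return (out, None) if with_cache else out
    k, d = params.k, params.char_table.dim
    half = k // 2
    chars = list(word)
    idx = [params.char_table.index(c) for c in chars]
    pad_i = params.char_table.pad_index
    padded = [pad_i] * half + idx + [pad_i] * half
    emb = params.char_table.param.value[padded]          # (T + k - 1, d)
    T = len(chars)
    # windows[i] = concat(e(c_{i-half}) ... e(c_{i+half}))
    windows = np.empty((T, k * d))
    for j in range(k):
        windows[:, j * d:(j + 1) * d] = emb[j:j + T]
    pre = windows @ params.W1.value.T + params.b1.value  # (T, N)
    act = np.maximum(pre, 0.0)
    argmax = act.argmax(axis=0)                          # first max per kernel
    out = act[argmax, np.arange(N)]
    if not with_cache:
        return out
    cache = (windows, pre, argmax, padded, T)
    return out, cache


def char_cnn_backward(grad_out: np.ndarray, cache, params: CharCNNParams) -> None:
    """Accumulate grads for W1, b1 and the character table for one word."""
    if cache is None:  # empty word produced a constant zero vector
        return
    windows, pre, argmax, padded, T = cache
    k, d, N = params.k, params.char_table.dim, params.N
    # route each kernel's gradient to its argmax position, through relu
    d_pre = np.zeros_like(pre)
    rows = argmax
    cols = np.arange(N)
    relu_open = pre[rows, cols] > 0.0
    d_pre[rows[relu_open], cols[relu_open]] = grad_out[cols[relu_open]]
    params.W1.grad += d_pre.T @ windows
    params.b1.grad += d_pre.sum(axis=0)
    d_windows = d_pre @ params.W1.value                  # (T, k*d)
    d_emb = np.zeros((T + k - 1, d))
    for j in range(k):
        d_emb[j:j + T] += d_windows[:, j * d:(j + 1) * d]
    params.char_table.backward(padded, d_emb)


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMParams:
    """Gate weights acting on the concatenation ``[h_{t-1}, x_t]``.

    ``W_f``, ``W_i``, ``W_o`` gate the forget, input and output paths;
    ``W_c`` produces the candidate cell state.  All have shape
    ``(hidden, hidden + input_dim)``.
    """

    W_f: Param
    W_i: Param
    W_o: Param
    W_c: Param
    b_f: Param
    b_i: Param
    b_o: Param
    b_c: Param
    hidden: int
    input_dim: int

    @classmethod
    def create(
        cls, input_dim: int, hidden: int, rng: np.random.Generator, *,
        prefix: str = "lstm",
    ) -> "LSTMParams":
        z = hidden + input_dim
        mk = lambda g: Param(f"{prefix}_W{g}", glorot_uniform(hidden, z, rng))
        mb = lambda g: Param(f"{prefix}_b{g}", np.zeros(hidden))
        return cls(mk("f"), mk("i"), mk("o"), mk("c"),
                   mb("f"), mb("i"), mb("o"), mb("c"), hidden, input_dim)

    def params(self) -> list[Param]:
        return [self.W_f, self.W_i, self.W_o, self.W_c,
                self.b_f, self.b_i, self.b_o, self.b_c]


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray, params: LSTMParams,
    *, with_cache: bool = False,
):
    """One LSTM step: forget/input/output gates and cell update.

    f = sigma(W_f [h,x] + b_f); i = sigma(W_i [h,x] + b_i);
    o = sigma(W_o [h,x] + b_o); C = f*C_prev + i*tanh(W_c [h,x] + b_c);
    h = o * tanh(C).
    """
    if x_t.shape[-1] != params.input_dim or h_prev.shape[-1] != params.hidden:
        raise ValueError("lstm_step dimension mismatch")
    z = np.concatenate([h_prev, x_t])
    f = _sigmoid(params.W_f.value @ z + params.b_f.value)
    i = _sigmoid(params.W_i.value @ z + params.b_i.value)
    o = _sigmoid(params.W_o.value @ z + params.b_o.value)
    g = np.tanh(params.W_c.value @ z + params.b_c.value)
    C = f * C_prev + i * g
    tC = np.tanh(C)
    h = o * tC
    if not with_cache:
        return h, C
    return h, C, (z, f, i, o, g, C_prev, tC)


def lstm_forward(inputs: np.ndarray, params: LSTMParams):
    """Run an LSTM over a sequence; returns (H, caches) with H of shape (n, hidden)."""
    n = inputs.shape[0]
    H = np.zeros((n, params.hidden))
    h = np.zeros(params.hidden)
    C = np.zeros(params.hidden)
    caches = []
    for t in range(n):
        h, C, cache = lstm_step(inputs[t], h, C, params, with_cache=True)
        H[t] = h
        caches.append(cache)
    return H, caches


def lstm_backward(
    d_H: np.ndarray, caches, params: LSTMParams
) -> np.ndarray:
    """BPTT through :func:`lstm_forward`; returns gradient wrt the inputs."""
    n = d_H.shape[0]
    hidden, input_dim = params.hidden, params.input_dim
    d_inputs = np.zeros((n, input_dim))
    dh_next = np.zeros(hidden)
    dC_next = np.zeros(hidden)
    for t in range(n - 1, -1, -1):
        z, f, i, o, g, C_prev, tC = caches[t]
        dh = d_H[t] + dh_next
        do = dh * tC
        dC = dh * o * (1.0 - tC * tC) + dC_next
        df = dC * C_prev
        di = dC * g
        dg = dC * i
        dC_next = dC * f
        # pre-activation grads
        d_af = df * f * (1.0 - f)
        d_ai = di * i * (1.0 - i)
        d_ao = do * o * (1.0 - o)
        d_ag = dg * (1.0 - g * g)
        params.W_f.grad += np.outer(d_af, z)
        params.W_i.grad += np.outer(d_ai, z)
        params.W_o.grad += np.outer(d_ao, z)
        params.W_c.grad += np.outer(d_ag, z)
        params.b_f.grad += d_af
        params.b_i.grad += d_ai
        params.b_o.grad += d_ao
        params.b_c.grad += d_ag
        dz = (params.W_f.value.T @ d_af + params.W_i.value.T @ d_ai
              + params.W_o.value.T @ d_ao + params.W_c.value.T @ d_ag)
        dh_next = dz[:hidden]
        d_inputs[t] = dz[hidden:]
    return d_inputs


def bilstm_encode(
    inputs: np.ndarray, fwd: LSTMParams, bwd: LSTMParams, *, with_cache: bool = False
):
    """Bidirectional encoding: ``h_t = [fwd_h_t ; bwd_h_t]``.

    The forward half at position t depends only on inputs 1..t, the backward
    half only on t..n.  Raises on an empty sequence.
    """
    if inputs.shape[0] == 0:
        raise ValueError("bilstm_encode requires a non-empty sequence")
    Hf, cf = lstm_forward(inputs, fwd)
    Hb_rev, cb = lstm_forward(inputs[::-1], bwd)
    Hb = Hb_rev[::-1]
    H = np.concatenate([Hf, Hb], axis=1)
    if not with_cache:
        return H
    return H, (cf, cb)


def bilstm_backward(
    d_H: np.ndarray, cache, fwd: LSTMParams, bwd: LSTMParams
) -> np.ndarray:
    cf, cb = cache
    hidden = fwd.hidden
    d_in_f = lstm_backward(d_H[:, :hidden], cf, fwd)
    d_in_b_rev = lstm_backward(d_H[::-1, hidden:], cb, bwd)
    return d_in_f + d_in_b_rev[::-1]


# ---------------------------------------------------------------------------
# Affine projection and dropout
# ---------------------------------------------------------------------------

class Affine:
    """y = x W^T + b, Glorot-initialized weights, zero bias."""

    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator, *,
        name: str = "proj",
    ) -> None:
        self.W = Param(f"{name}_W", glorot_uniform(out_dim, in_dim, rng))
        self.b = Param(f"{name}_b", np.zeros(out_dim))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.value.T + self.b.value

    def backward(self, x: np.ndarray, d_out: np.ndarray) -> np.ndarray:
        self.W.grad += d_out.T @ x
        self.b.grad += d_out.sum(axis=0)
        return d_out @ self.W.value

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Dropout:
    """Inverted dropout: active only in train mode; identity at rate 0."""

    def __init__(self, rate: float) -> None:
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator, train: bool):
        if not train or self.rate == 0.0:
            return x, None
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask, mask

    @staticmethod
    def backward(d_out: np.ndarray, mask) -> np.ndarray:
        return d_out if mask is None else d_out * mask
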