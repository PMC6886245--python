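"""Linear-chain CRF: path scoring, log-partition, NLL and Viterbi decoding.

The score of a tag path y for a sentence of length n is

    S(X, y) = sum_{i=0..n} T[y_i, y_{i+1}] + sum_{i=1..n} P[i, y_i]

where P is the n x m emission matrix from the encoder and T is an
(m+2) x (m+2) transition matrix augmented with a start state (index m) and
an end state (index m+1); y_0 = start and y_{n+1} = end.  Transitions into
start and out of end are masked with a large negative score and never
learned.  The normalizer log Z = log sum over all m^n paths of exp S is
computed by a log-space forward recursion, equivalent to (but never
materializing) the full softmax over paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CRFParams",
    "MASK_SCORE",
    "path_score",
    "log_partition",
    "crf_nll",
    "crf_nll_grad",
    "viterbi_decode",
]

MASK_SCORE = -1.0e4


@dataclass
class CRFParams:
    """Augmented transition matrix over ``tag_alphabet`` + {start, end}."""

    T: np.ndarray
    tag_alphabet: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.tag_alphabet)

    @property
    def start(self) -> int:
        return self.m

    @property
    def end(self) -> int:
        return self.m + 1

    @classmethod
    def create(cls, tag_alphabet: tuple[str, ...]) -> "CRFParams":
        m = len(tag_alphabet)
        T = np.zeros((m + 2, m + 2))
        crf = cls(T, tuple(tag_alphabet))
        crf.apply_mask()
        return crf

    def apply_mask(self) -> None:
        """Forbid transitions into start and out of end (and start->start etc.)."""
        self.T[:, self.start] = MASK_SCORE
        self.T[self.end, :] = MASK_SCORE
        self.T[self.start, self.end] = MASK_SCORE  # no empty path

    def mask_grad(self, grad: np.ndarray) -> None:
        grad[:, self.start] = 0.0
        grad[self.end, :] = 0.0
        grad[self.start, self.end] = 0.0


def _check(P: np.ndarray, crf: CRFParams) -> None:
    if P.ndim != 2 or P.shape[1] != crf.m:
        raise ValueError(f"emission matrix shape {P.shape} != (n, {crf.m})")


def path_score(P: np.ndarray, crf: CRFParams, y: list[int]) -> float:
    """S(X, y) including the start->y_1 and y_n->end transitions."""
    _check(P, crf)
    n = P.shape[0]
    if len(y) != n:
        raise ValueError("path length != sentence length")
    if any(not (0 <= t < crf.m) for t in y):
        raise ValueError("tag index out of range")
    T = crf.T
    s = T[crf.start, y[0]] + P[np.arange(n), y].sum() + T[y[-1], crf.end]
    for i in range(n - 1):
        s += T[y[i], y[i + 1]]
    return float(s)


def log_partition(P: np.ndarray, crf: CRFParams) -> float:
    """log Z via the log-space forward recursion over tag lattices."""
    _check(P, crf)
    n, m = P.shape
    if n == 0:
        raise ValueError("empty sentence")
    T = crf.T
    alpha = T[crf.start, :m] + P[0]
    trans = T[:m, :m]
    for t in range(1, n):
        alpha = logsumexp(alpha[:, None] + trans, axis=0) + P[t]
    return float(logsumexp(alpha + T[:m, crf.end]))


def crf_nll(P: np.ndarray, crf: CRFParams, y_gold: list[int]) -> float:
    """Negative log-likelihood -[S(X, y_gold) - log Z]; always >= 0."""
    return log_partition(P, crf) - path_score(P, crf, y_gold)


def _forward_backward(P: np.ndarray, crf: CRFParams):
    n, m = P.shape
    T = crf.T
    trans = T[:m, :m]
    alphas = np.empty((n, m))
    alphas[0] = T[crf.start, :m] + P[0]
    for t in range(1, n):
        alphas[t] = logsumexp(alphas[t - 1][:, None] + trans, axis=0) + P[t]
    betas = np.empty((n, m))
    betas[n - 1] = T[:m, crf.end]
    for t in range(n - 2, -1, -1):
        betas[t] = logsumexp(trans + (P[t + 1] + betas[t + 1])[None, :], axis=1)
    logZ = float(logsumexp(alphas[n - 1] + betas[n - 1]))
    return alphas, betas, logZ


def crf_nll_grad(
    P: np.ndarray, crf: CRFParams, y_gold: list[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL and its analytic gradients wrt P and T (expected minus observed counts)."""
    _check(P, crf)
    n, m = P.shape
    alphas, betas, logZ = _forward_backward(P, crf)
    # unary marginals
    gamma = np.exp(alphas + betas - logZ)            # (n, m)
    dP = gamma.copy()
    dP[np.arange(n), y_gold] -= 1.0
    dT = np.zeros_like(crf.T)
    trans = crf.T[:m, :m]
    # pairwise expected counts
    for t in range(n - 1):
        xi = np.exp(
            alphas[t][:, None] + trans + (P[t + 1] + betas[t + 1])[None, :] - logZ
        )
        dT[:m, :m] += xi
    # start and end transitions
    p_first = np.exp(crf.T[crf.start, :m] + P[0] + betas[0] - logZ)
    dT[crf.start, :m] += p_first
    p_last = np.exp(alphas[n - 1] + crf.T[:m, crf.end] - logZ)
    dT[:m, crf.end] += p_last
    # subtract observed (gold) counts
    dT[crf.start, y_gold[0]] -= 1.0
    for t in range(n - 1):
        dT[y_gold[t], y_gold[t + 1]] -= 1.0
    dT[y_gold[-1], crf.end] -= 1.0
    crf.mask_grad(dT)
    nll = logZ - path_score(P, crf, y_gold)
    return nll, dP, dT


def viterbi_decode(P: np.ndarray, crf: CRFParams) -> tuple[list[int], float]:
    """Best path y* = argmax S(X, y) and its score, by dynamic programming.

    Ties break toward the lowest tag index (first argmax).
    """
    _check(P, crf)
    n, m = P.shape
    if n == 0:
        return [], 0.0
    T = crf.T
    trans = T[:m, :m]
    delta = T[crf.start, :m] + P[0]
    back = np.zeros((n, m), dtype=np.intp)
    for t in range(1, n):
        scores = delta[:, None] + trans          # (prev, cur)
        back[t] = scores.argmax(axis=0)
        delta = scores[back[t], np.arange(m)] + P[t]
    delta = delta + T[:m, crf.end]
    last = int(delta.argmax())
    best_score = float(delta[last])
    path = [last]
    for t in range(n - 1, 0, -1):
        last = int(back[t, last])
        path.append(last)
    path.reverse()
    return path, best_score
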