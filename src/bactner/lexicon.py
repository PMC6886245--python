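"""Gazetteer features: token-trie lexicon and bidirectional maximum matching.

A :class:`Lexicon` is a set of multi-token names (e.g. bacterial binomials)
indexed by a token-sequence trie.  Matching is case-insensitive after NFC
normalization by default; token boundaries are exact — no sub-token matches.

The dictionary feature column is produced by bidirectional maximum matching
(BDMM): a greedy longest-first scan run left-to-right and right-to-left,
with a conflict rule choosing between the two match sets.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal

from .corpus import EntitySpan, Sentence, spans_to_tags

__all__ = [
    "Lexicon",
    "Match",
    "load_lexicon",
    "forward_max_match",
    "backward_max_match",
    "bdmm_tag",
    "attach_pos",
]

logger = logging.getLogger(__name__)

Direction = Literal["forward", "backward"]


def _norm(token: str, case_fold: bool) -> str:
    token = unicodedata.normalize("NFC", token)
    return token.casefold() if case_fold else token


@dataclass(frozen=True)
class Match:
    """One dictionary match: the token span plus the scan direction."""

    span: EntitySpan
    direction: Direction


class Lexicon:
    """A set of token sequences with a prefix trie and known maximum length.

    Parameters
    ----------
    entries:
        Iterable of token tuples (already tokenized names).
    case_fold:
        Match case-insensitively (default).  Entries are normalized on
        insertion; queries are normalized in :meth:`contains`.
    """

    def __init__(
        self, entries: Iterable[tuple[str, ...]] = (), *, case_fold: bool = True
    ) -> None:
        self.case_fold = case_fold
        self._entries: set[tuple[str, ...]] = set()
        self._trie: dict = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: tuple[str, ...]) -> None:
        if not entry:
            raise ValueError("lexicon entry must have >= 1 token")
        key = tuple(_norm(t, self.case_fold) for t in entry)
        self._entries.add(key)
        node = self._trie
        for tok in key:
            node = node.setdefault(tok, {})
        node[None] = True  # terminal marker

    @property
    def entries(self) -> frozenset[tuple[str, ...]]:
        return frozenset(self._entries)

    @property
    def L_max(self) -> int:
        """Maximum entry length in tokens (0 for an empty lexicon)."""
        return max((len(e) for e in self._entries), default=0)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, entry: tuple[str, ...]) -> bool:
        return tuple(_norm(t, self.case_fold) for t in entry) in self._entries

    def longest_prefix_match(self, tokens: list[str], start: int) -> int:
        """Length of the longest entry starting at *start*, or 0."""
        node = self._trie
        best = 0
        limit = min(len(tokens), start + self.L_max)
        for i in range(start, limit):
            tok = _norm(tokens[i], self.case_fold)
            node = node.get(tok)
            if node is None:
                break
            if None in node:
                best = i - start + 1
        return best


def load_lexicon(
    path: str | Path, *, case_fold: bool = True, tokenizer: Callable[[str], list[str]] = str.split
) -> Lexicon:
    """Load a lexicon from a UTF-8 text file, one name per line.

    Names are tokenized by whitespace (or *tokenizer*), case-folded and
    NFC-normalized; duplicate entries collapse.  An empty file yields a valid
    empty lexicon with a warning.
    """
    path = Path(path)
    lex = Lexicon(case_fold=case_fold)
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            toks = tokenizer(line.strip())
            if toks:
                lex.add(tuple(toks))
    if len(lex) == 0:
        logger.warning("lexicon file %s produced an empty lexicon", path)
    return lex


def forward_max_match(tokens: list[str], lex: Lexicon) -> list[Match]:
    """Greedy longest-first dictionary matching scanning left to right.

    At each position take the longest lexicon entry starting there (at most
    ``L_max`` tokens); on a match jump past it.  Matches are disjoint.
    """
    matches: list[Match] = []
    i = 0
    n = len(tokens)
    while i < n:
        length = lex.longest_prefix_match(tokens, i)
        if length > 0:
            matches.append(Match(EntitySpan(i, i + length, "bacteria"), "forward"))
            i += length
        else:
            i += 1
    return matches


def backward_max_match(tokens: list[str], lex: Lexicon) -> list[Match]:
    """Mirror of :func:`forward_max_match`: scan right to left, taking the
    longest entry that *ends* at the cursor."""
    matches: list[Match] = []
    n = len(tokens)
    j = n
    while j > 0:
        best = 0
        for length in range(min(lex.L_max, j), 0, -1):
            if tuple(tokens[j - length : j]) in lex:
                best = length
                break
        if best > 0:
            matches.append(Match(EntitySpan(j - best, j, "bacteria"), "backward"))
            j -= best
        else:
            j -= 1
    matches.reverse()
    return matches


def _coverage(matches: list[Match]) -> int:
    return sum(m.span.end - m.span.start for m in matches)


def bdmm_tag(tokens: list[str], lex: Lexicon, etype: str = "bacteria") -> list[str]:
    """Dictionary feature column via bidirectional maximum matching.

    Runs both scan directions and keeps one match set: the direction with
    greater total matched-token coverage; on a tie, the one with fewer
    matches (longer average match); on a final tie, the backward result.
    Emits IOB2 tags (``B-<etype>``/``I-<etype>``/``O``).
    """
    fwd = forward_max_match(tokens, lex)
    bwd = backward_max_match(tokens, lex)
    cf, cb = _coverage(fwd), _coverage(bwd)
    if cf > cb:
        chosen = fwd
    elif cb > cf:
        chosen = bwd
    elif len(fwd) < len(bwd):
        chosen = fwd
    else:
        chosen = bwd
    spans = [EntitySpan(m.span.start, m.span.end, etype) for m in chosen]
    return spans_to_tags(spans, len(tokens))


def attach_pos(sentence: Sentence, tagger: Callable[[list[str]], list[str]]) -> Sentence:
    """Fill the POS column using a pluggable tagger.

    *tagger* maps a surface list to an equal-length POS list.  Tokens whose
    POS column is already non-empty (e.g. read from file) are left untouched.
    Raises ``ValueError`` if the tagger returns the wrong length.
    """
    from dataclasses import replace

    surfaces = sentence.surfaces
    if not surfaces:
        return sentence
    pos = tagger(surfaces)
    if len(pos) != len(surfaces):
        raise ValueError(
            f"tagger returned {len(pos)} tags for {len(surfaces)} tokens"
        )
    new_tokens = tuple(
        tok if tok.pos else replace(tok, pos=p)
        for tok, p in zip(sentence.tokens, pos)
    )
    return Sentence(new_tokens)
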