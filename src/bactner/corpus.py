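"""CoNLL-style corpus I/O and IOB2 tag/span conversion.

The corpus format is a 4-column TSV: ``token<TAB>pos<TAB>dict<TAB>tag``, one
token per line, sentences separated by a blank line.  A reduced 2-column form
(``token<TAB>tag``) is accepted on read; missing feature columns are filled
with the empty string.

Token indices are 0-based and entity spans are half-open ``[start, end)``.
Tags follow the IOB2 scheme: ``B-X`` opens an entity of type ``X``, ``I-X``
continues it, ``O`` is outside any entity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Token",
    "Sentence",
    "Corpus",
    "EntitySpan",
    "CorpusFormatError",
    "read_conll",
    "write_conll",
    "tags_to_spans",
    "spans_to_tags",
    "repair_iob2",
    "validate_iob2",
]

_IOB2_RE = re.compile(r"^(O|[BI]-\S+)$")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or invalid tag shapes."""


@dataclass(frozen=True)
class Token:
    """A single token with its surface form and per-token features."""

    surface: str
    pos: str = ""
    dict_feat: str = ""
    gold_tag: str = "O"

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")


@dataclass(frozen=True)
class Sentence:
    """An ordered sequence of tokens."""

    tokens: tuple[Token, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    @property
    def gold_tags(self) -> list[str]:
        return [t.gold_tag for t in self.tokens]

    @property
    def dict_feats(self) -> list[str]:
        return [t.dict_feat for t in self.tokens]

    @property
    def pos_tags(self) -> list[str]:
        return [t.pos for t in self.tokens]


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of sentences plus the observed tag alphabet."""

    sentences: tuple[Sentence, ...]
    tag_alphabet: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.tag_alphabet:
            object.__setattr__(self, "tag_alphabet", _collect_tags(self.sentences))
        alphabet = set(self.tag_alphabet)
        for sent in self.sentences:
            for tok in sent:
                if tok.gold_tag not in alphabet:
                    raise ValueError(
                        f"tag {tok.gold_tag!r} not in tag alphabet {sorted(alphabet)}"
                    )

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed half-open token interval ``[start, end)``."""

    start: int
    end: int
    etype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def _collect_tags(sentences: Iterable[Sentence]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for sent in sentences:
        for tok in sent:
            seen.setdefault(tok.gold_tag, None)
    return tuple(seen)


def _check_tag_shape(tag: str, lineno: int, path: Path) -> None:
    if not _IOB2_RE.match(tag):
        raise CorpusFormatError(
            f"{path}:{lineno}: tag {tag!r} does not match IOB2 shape "
            "(expected 'O' or 'B-TYPE'/'I-TYPE')"
        )


def read_conll(path: str | Path) -> Corpus:
    """Read a 4-column (or 2-column) CoNLL-style file into a :class:`Corpus`.

    Blank lines separate sentences; trailing blank lines produce no empty
    sentence.  Raises :class:`CorpusFormatError` with the offending line
    number on malformed input.
    """
    path = Path(path)
    sentences: list[Sentence] = []
    current: list[Token] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if current:
                    sentences.append(Sentence(tuple(current)))
                    current = []
                continue
            cols = line.split("\t")
            if len(cols) == 4:
                surface, pos, dict_feat, tag = cols
            elif len(cols) == 2:
                surface, tag = cols
                pos = dict_feat = ""
            else:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 or 4 tab-separated columns, "
                    f"got {len(cols)}"
                )
            _check_tag_shape(tag, lineno, path)
            if dict_feat:
                _check_tag_shape(dict_feat, lineno, path)
            current.append(Token(surface, pos, dict_feat, tag))
    if current:
        sentences.append(Sentence(tuple(current)))
    return Corpus(tuple(sentences))


def write_conll(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the 4-column format; inverse of :func:`read_conll`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in corpus:
            for tok in sent:
                fh.write(f"{tok.surface}\t{tok.pos}\t{tok.dict_feat}\t{tok.gold_tag}\n")
            fh.write("\n")


@dataclass
class RepairLog:
    """Counter of IOB2 repairs applied (orphan I -> B)."""

    count: int = 0
    positions: list[int] = field(default_factory=list)


def repair_iob2(tags: list[str], log: RepairLog | None = None) -> list[str]:
    """Apply the IOB2 repair convention: an ``I-X`` not preceded by ``B-X`` or
    ``I-X`` of the same type is re-read as ``B-X``.  Repairs are counted in
    *log* when given."""
    out: list[str] = []
    prev = "O"
    for i, tag in enumerate(tags):
        if tag.startswith("I-"):
            etype = tag[2:]
            if not (prev == f"B-{etype}" or prev == f"I-{etype}"):
                tag = f"B-{etype}"
                if log is not None:
                    log.count += 1
                    log.positions.append(i)
        out.append(tag)
        prev = tag
    return out


def validate_iob2(tags: list[str]) -> bool:
    """True iff *tags* is a well-formed IOB2 sequence (no orphan I)."""
    log = RepairLog()
    repair_iob2(tags, log)
    return log.count == 0 and all(_IOB2_RE.match(t) for t in tags)


def tags_to_spans(tags: list[str], log: RepairLog | None = None) -> list[EntitySpan]:
    """Decode an IOB2 tag sequence into entity spans.

    Each maximal ``B-X (I-X)*`` run becomes one span.  Invalid sequences are
    repaired first (orphan ``I`` read as ``B``); repairs are counted in *log*.
    Output spans are disjoint and sorted by start.
    """
    tags = repair_iob2(list(tags), log)
    spans: list[EntitySpan] = []
    start = None
    etype = None
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, etype))
            start, etype = i, tag[2:]
        elif tag.startswith("I-"):
            pass  # guaranteed same-type continuation after repair
        else:  # O
            if start is not None:
                spans.append(EntitySpan(start, i, etype))
                start = None
    if start is not None:
        spans.append(EntitySpan(start, len(tags), etype))
    return spans


def spans_to_tags(spans: list[EntitySpan], n: int) -> list[str]:
    """Encode non-overlapping spans as an IOB2 tag sequence of length *n*.

    Raises ``ValueError`` on overlapping or out-of-range spans.
    """
    tags = ["O"] * n
    last_end = -1
    for span in sorted(spans):
        if span.end > n:
            raise ValueError(f"span {span} exceeds sentence length {n}")
        if span.start < last_end:
            raise ValueError(f"span {span} overlaps a previous span")
        tags[span.start] = f"B-{span.etype}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.etype}"
        last_end = span.end
    return tags


def with_dict_feats(sentence: Sentence, feats: list[str]) -> Sentence:
    """Return a copy of *sentence* with the dict-feature column replaced."""
    if len(feats) != len(sentence):
        raise ValueError("feature length mismatch")
    return Sentence(
        tuple(replace(t, dict_feat=f) for t, f in zip(sentence.tokens, feats))
    )


def with_gold_tags(sentence: Sentence, tags: list[str]) -> Sentence:
    """Return a copy of *sentence* with the gold-tag column replaced."""
    if len(tags) != len(sentence):
        raise ValueError("tag length mismatch")
    return Sentence(
        tuple(replace(t, gold_tag=g) for t, g in zip(sentence.tokens, tags))
    )
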