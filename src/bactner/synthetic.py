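"""Seeded synthetic corpora and lexicons for end-to-end testing.

The generator emulates the statistical structure the tagger assumes in
microbiome abstracts: multi-token bacterial binomials (a capitalized
pseudo-Latin genus followed by a lowercase species epithet) embedded in
non-entity filler text, with a controllable fraction of entity mentions
drawn from *outside* the emitted lexicon (so the dictionary feature is
absent and the model must rely on word shape and context).  POS tags come
from fixed templates, so no external tagger is needed.

Everything is deterministic under (config, seed): the same inputs produce
byte-identical corpus files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, EntitySpan, Sentence, Token, spans_to_tags, tags_to_spans
from .lexicon import Lexicon, bdmm_tag

__all__ = ["SynthConfig", "generate_lexicon", "generate_corpus", "corpus_stats"]

# latinate morphemes for genus/species construction
_GENUS_HEADS = [
    "lacto", "strepto", "staphylo", "entero", "porphyro", "actino", "pepto",
    "fuso", "myco", "bifido", "clostri", "pseudo", "rhodo", "thermo", "vibrio",
    "campylo", "helico", "neisse", "prevo", "bacter",
]
_GENUS_TAILS = [
    "bacillus", "coccus", "monas", "bacterium", "spira", "myces", "vibrio",
    "plasma", "phila", "coides",
]
_SPECIES = [
    "acidophilus", "gingivalis", "mutans", "aureus", "coli", "nucleatum",
    "micros", "pylori", "subtilis", "cereus", "fragilis", "longum",
    "casei", "plantarum", "oralis", "salivarius", "sanguinis", "mitis",
    "denticola", "forsythia", "intermedia", "rectus", "gordonii", "naeslundii",
]

# filler vocabulary with template POS tags (Penn Treebank style)
_FILLER: list[tuple[str, str]] = [
    ("the", "DT"), ("a", "DT"), ("this", "DT"), ("these", "DT"),
    ("study", "NN"), ("infection", "NN"), ("biofilm", "NN"), ("plaque", "NN"),
    ("abundance", "NN"), ("prevalence", "NN"), ("strain", "NN"), ("sample", "NN"),
    ("patients", "NNS"), ("subjects", "NNS"), ("lesions", "NNS"), ("cultures", "NNS"),
    ("was", "VBD"), ("were", "VBD"), ("showed", "VBD"), ("increased", "VBD"),
    ("detected", "VBN"), ("isolated", "VBN"), ("associated", "VBN"),
    ("is", "VBZ"), ("remains", "VBZ"),
    ("significantly", "RB"), ("frequently", "RB"), ("often", "RB"),
    ("oral", "JJ"), ("periodontal", "JJ"), ("subgingival", "JJ"), ("clinical", "JJ"),
    ("in", "IN"), ("of", "IN"), ("with", "IN"), ("from", "IN"), ("among", "IN"),
    ("and", "CC"), ("or", "CC"), ("but", "CC"),
    (",", ","), (";", ":"),
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic corpus.

    ``oov_entity_rate`` is the fraction of entity mentions drawn from a
    held-back name pool that never enters the emitted lexicon;
    ``abbrev_rate`` renders a mention as ``X. species``.  Entity mentions
    are 2-token binomials except for the configured fractions of 1- and
    3-token names.
    """

    n_genera: int = 20
    n_species_per_genus: int = 5
    n_sentences: int = 500
    min_len: int = 6
    max_len: int = 20
    max_entities_per_sentence: int = 3
    oov_entity_rate: float = 0.3
    abbrev_rate: float = 0.1
    mono_rate: float = 0.05   # 1-token mentions (genus alone)
    tri_rate: float = 0.05    # 3-token mentions (binomial + "subsp")
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.oov_entity_rate, self.abbrev_rate, self.mono_rate, self.tri_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        for name in ("n_genera", "n_species_per_genus", "n_sentences",
                     "min_len", "max_len", "max_entities_per_sentence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")


def _make_genus(rng: np.random.Generator) -> str:
    head = _GENUS_HEADS[rng.integers(len(_GENUS_HEADS))]
    tail = _GENUS_TAILS[rng.integers(len(_GENUS_TAILS))]
    return (head + tail).capitalize()


def generate_names(cfg: SynthConfig, rng: np.random.Generator, n_extra_genera: int = 0
                   ) -> list[tuple[str, str]]:
    """Unique (genus, species) binomials; first cfg.n_genera genera are
    in-lexicon material, the extras feed the out-of-lexicon pool."""
    genera: list[str] = []
    seen = set()
    while len(genera) < cfg.n_genera + n_extra_genera:
        g = _make_genus(rng)
        if g not in seen:
            seen.add(g)
            genera.append(g)
    names = []
    for g in genera:
        eps = rng.choice(len(_SPECIES), size=cfg.n_species_per_genus, replace=False)
        for e in eps:
            names.append((g, _SPECIES[e]))
    return names


def generate_lexicon(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[Lexicon, list[tuple[str, str]]]:
    """Build the in-dictionary name list and its Lexicon."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    names = generate_names(cfg, rng)
    lex = Lexicon((tuple(n) for n in names))
    return lex, names


def _render_mention(
    name: tuple[str, str], cfg: SynthConfig, rng: np.random.Generator
) -> list[str]:
    genus, species = name
    u = rng.random()
    if u < cfg.mono_rate:
        return [genus]
    if u < cfg.mono_rate + cfg.tri_rate:
        return [genus, species, "subsp"]
    if rng.random() < cfg.abbrev_rate:
        return [f"{genus[0]}.", species]
    return [genus, species]


@dataclass
class GenerationInfo:
    """Generator bookkeeping: mention counts by provenance."""

    n_mentions: int = 0
    n_oov_mentions: int = 0

    @property
    def oov_fraction(self) -> float:
        return self.n_oov_mentions / self.n_mentions if self.n_mentions else 0.0


def generate_corpus(
    cfg: SynthConfig,
    lex: Lexicon | None = None,
    rng: np.random.Generator | None = None,
    *,
    names: list[tuple[str, str]] | None = None,
    info: GenerationInfo | None = None,
) -> Corpus:
    """Generate a gold-tagged 4-column corpus.

    Entity mentions are sampled from the lexicon names or, with probability
    ``oov_entity_rate``, from a disjoint out-of-lexicon pool.  The dict
    column is produced by running BDMM against *lex*, so in-lexicon
    mentions carry B/I dictionary features while OOV mentions read O — the
    supervision mismatch the model must overcome.  Pass an *info* record to
    receive mention counts.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if names is None:
        all_names = generate_names(cfg, rng, n_extra_genera=max(2, cfg.n_genera // 2))
        n_in = cfg.n_genera * cfg.n_species_per_genus
        names = all_names[:n_in]
        oov_pool = all_names[n_in:]
        if lex is None:
            lex = Lexicon(tuple(n) for n in names)
    else:
        if lex is None:
            lex = Lexicon(tuple(n) for n in names)
        extra = generate_names(cfg, rng, n_extra_genera=max(2, cfg.n_genera // 2))
        oov_pool = [n for n in extra if tuple(n) not in lex.entries]
    oov_pool = [n for n in oov_pool if tuple(n) not in lex.entries]
    if len(lex) == 0:
        raise ValueError("lexicon must be non-empty")
    pos_of = dict(_FILLER)
    filler_words = [w for w, _ in _FILLER]

    sentences = []
    for _ in range(cfg.n_sentences):
        length = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        n_ent = int(rng.integers(0, cfg.max_entities_per_sentence + 1))
        surface: list[str] = [
            filler_words[rng.integers(len(filler_words))] for _ in range(length)
        ]
        pos: list[str] = [pos_of[w] for w in surface]
        spans: list[EntitySpan] = []
        # place entity mentions left to right at random gaps
        cursor = int(rng.integers(0, 3))
        for _ in range(n_ent):
            is_oov = bool(rng.random() < cfg.oov_entity_rate) and bool(oov_pool)
            if is_oov:
                name = oov_pool[rng.integers(len(oov_pool))]
            else:
                name = names[rng.integers(len(names))]
            mention = _render_mention(name, cfg, rng)
            if cursor + len(mention) > length:
                break
            for k, tok in enumerate(mention):
                surface[cursor + k] = tok
                pos[cursor + k] = "NNP" if k == 0 else "NN"
            spans.append(EntitySpan(cursor, cursor + len(mention), "bacteria"))
            if info is not None:
                info.n_mentions += 1
                info.n_oov_mentions += int(is_oov)
            cursor += len(mention) + 1 + int(rng.integers(0, 3))
        gold = spans_to_tags(spans, length)
        dict_col = bdmm_tag(surface, lex)
        tokens = tuple(
            Token(s, p, d, g) for s, p, d, g in zip(surface, pos, dict_col, gold)
        )
        sentences.append(Sentence(tokens))
    return Corpus(tuple(sentences), tag_alphabet=("O", "B-bacteria", "I-bacteria"))


@dataclass
class CorpusStats:
    sentences: int
    tokens: int
    entities: int
    entity_tokens: int

    def format(self) -> str:
        return "\n".join(
            f"{k}\t{v}" for k, v in vars(self).items()
        )


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Summary counts: sentences, tokens, entities, entity tokens."""
    entities = 0
    entity_tokens = 0
    for sent in corpus:
        spans = tags_to_spans(sent.gold_tags)
        entities += len(spans)
        entity_tokens += sum(s.end - s.start for s in spans)
    return CorpusStats(len(corpus), corpus.n_tokens, entities, entity_tokens)
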