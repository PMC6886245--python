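"""Reading the 4-column corpus format and decoding IOB2 tags into spans.

Builds the canonical three-pathogen example sentence, writes it in the
corpus format, reads it back and decodes the entity spans.
"""

import tempfile
from pathlib import Path

from bactner import Corpus, Sentence, Token, read_conll, tags_to_spans, write_conll

ROWS = [
    ("Actinobacillus", "NNP", "B-bacteria", "B-bacteria"),
    ("actinomycetemcomitans", "NNS", "I-bacteria", "I-bacteria"),
    (",", ",", "O", "O"),
    ("Porphyromonas", "NNP", "B-bacteria", "B-bacteria"),
    ("gingivalis", "NN", "I-bacteria", "I-bacteria"),
    (",", ",", "O", "O"),
    ("and", "CC", "O", "O"),
    ("Peptostreptococcus", "NNP", "B-bacteria", "B-bacteria"),
    ("micros", "NNS", "I-bacteria", "I-bacteria"),
]

corpus = Corpus((Sentence(tuple(Token(*r) for r in ROWS)),))

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "example.tsv"
    write_conll(corpus, path)
    reread = read_conll(path)
    assert reread == corpus

sent = reread.sentences[0]
print(f"{len(reread)} sentence, {len(sent)} tokens, "
      f"tag alphabet {sorted(reread.tag_alphabet)}")
for span in tags_to_spans(sent.gold_tags):
    name = " ".join(sent.surfaces[span.start:span.end])
    print(f"  entity tokens [{span.start}, {span.end}) -> {name!r}")
# Each B-...I-... run in the tag column becomes one half-open token span;
# the three oral pathogens come out as three exact entity intervals.
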