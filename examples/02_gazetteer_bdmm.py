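"""Dictionary features via bidirectional maximum matching (BDMM).

Loads a three-name bacterial lexicon and tags a sentence's tokens with
IOB2 dictionary features, then shows a case where the two scan directions
disagree and the conflict rule picks the higher-coverage one.
"""

from bactner import Lexicon, bdmm_tag, backward_max_match, forward_max_match

lex = Lexicon([
    ("Actinobacillus", "actinomycetemcomitans"),
    ("Porphyromonas", "gingivalis"),
    ("Peptostreptococcus", "micros"),
])
tokens = ("Actinobacillus actinomycetemcomitans , Porphyromonas gingivalis , "
          "and Peptostreptococcus micros").split()
print("dict feature column:", bdmm_tag(tokens, lex))
# B/I mark tokens covered by a lexicon name; O is everything else.

# a crafted conflict: forward matching covers 3 tokens, backward only 2
tricky = Lexicon([("a", "b"), ("b", "c"), ("c",)])
toks = ["a", "b", "c"]
fwd = [(m.span.start, m.span.end) for m in forward_max_match(toks, tricky)]
bwd = [(m.span.start, m.span.end) for m in backward_max_match(toks, tricky)]
print(f"forward matches {fwd} (coverage 3), backward matches {bwd} (coverage 2)")
print("BDMM keeps the direction with greater coverage:", bdmm_tag(toks, tricky))
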