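# Methods

`bactner` tags bacterial name mentions in tokenized biomedical text with a
hybrid sequence model: per-token embeddings assembled from four sources, a
bidirectional LSTM encoder, and a linear-chain CRF decoder, supported by a
gazetteer feature computed with bidirectional maximum matching and evaluated
by strict span-level F1.  This note records the model, its parameters, the
numerical choices, what the synthetic data does and does not emulate, and
the design decisions taken where more than one reading was defensible.

## Model

**Embedding layer.**  Each token x_t is represented by the concatenation of

1. a *word embedding* (default 300-dim): case-folded surface lookup; tokens
   outside the vocabulary map to a trainable UNK row.  Pre-trained vectors in
   word2vec text format can seed the table; rows are fine-tuned during
   training unless frozen.
2. a *character-level CNN* feature (30-dim): each character of the word is
   embedded (25-dim), a width-3 convolution with 30 kernels slides over the
   character sequence with same-padding (a dedicated pad symbol whose
   embedding is fixed at zero), each position passes through ReLU, and
   max-pooling over positions yields one value per kernel.  This captures
   prefix/suffix morphology — the latinate endings (-bacillus, -coccus,
   -ensis) that make bacterial names recognizable even out of dictionary.
   The empty word maps to the zero vector; one-character words are padded to
   a full window.
3. a *POS embedding* (25-dim): learned lookup over the Penn-Treebank-style
   tag observed in the corpus' POS column.  The tagger itself is a pluggable
   contract (any surfaces→tags callable); precomputed columns are used
   verbatim.
4. a *dictionary embedding* (5-dim): learned lookup over the IOB2 gazetteer
   feature (B-bacteria / I-bacteria / O) produced by BDMM (below).

**Encoder.**  A forward and a backward LSTM (100 hidden units each by
default) process the concatenated embeddings; each position's representation
is the concatenation [→h_t ; ←h_t].  The LSTM uses the standard
forget/input/output gate equations with sigmoid gates and tanh cell
candidate, all gates acting on [h_{t−1}, x_t].

**Decoder.**  An affine projection maps each 2·hidden encoder state to m
per-tag emission scores (the matrix P).  A path y through the tag lattice
scores

    S(X, y) = Σ_i T[y_i, y_{i+1}] + Σ_i P[i, y_i]

with a learned (m+2)×(m+2) transition matrix T augmented with start/end
states; the conditional path distribution is the softmax of S over all m^n
paths.  Training minimizes the negative log-likelihood of the gold path;
decoding is exact Viterbi.

## Gazetteer feature (BDMM)

The dictionary column is produced by greedy longest-first matching of the
token sequence against a lexicon of bacterial names, run in both directions:

- *forward*: scan left→right; at each position take the longest lexicon
  entry starting there (bounded by the lexicon's maximum entry length) and
  jump past it;
- *backward*: scan right→left, taking the longest entry ending at the cursor.

The two match sets can differ; the conflict rule keeps the direction with
greater total matched-token coverage, then (on a tie) the one with fewer
matches — i.e. longer average matches — and finally the backward result.
Matching is case-insensitive after NFC normalization, and token boundaries
are exact: no sub-token matches.  Both the tie-break and case behaviour are
configurable, since neither is canonical.

## Tagging scheme and evaluation

Tags are IOB2: every entity starts with B-TYPE.  Sequences read from
arbitrary predictors are repaired by the standard convention (an I-X with no
compatible predecessor is re-read as B-X), with repairs counted.  Spans are
half-open token intervals [start, end).

Evaluation is strict span-level micro-averaged precision / recall / F1:
an entity counts only on an exact (start, end, type) match; counts are
pooled over the corpus before P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R), reported as percentages at three decimals.  When a
denominator is zero the metric is 0 and the report carries a flag.  Partial
credit and token-level accuracy are deliberately not headline metrics.

## Training

- **Loss**: mean per-sentence CRF NLL over a mini-batch (default batch 16;
  padded positions never enter the loss, partition or Viterbi because each
  sentence is scored at its true length under the batch mask).
- **Optimizer**: Adam, learning rate 0.001, β₁ = 0.9, β₂ = 0.999.  The decay
  rate of 0.9 is applied as a per-epoch multiplicative learning-rate factor
  (lr ← 0.9·lr); the alternative reading — decay as Adam's β₁ — is available
  through configuration.  Gradients are clipped at global norm 5.0.
- **Dropout** 0.5, applied to the concatenated embedding (input to the
  encoder) and to the encoder output before the emission projection, i.e.
  bracketing the encoding layer.
- **Early stopping** on validation span-F1 with patience 5 and absolute
  tolerance 1e-4: training stops when five consecutive evaluations fail to
  beat the best F1, and the returned model carries the best epoch's
  parameters, not the last.
- **Initialization**: embedding tables uniform on [−√(3/dim), +√(3/dim)];
  convolution and fully-connected weights Glorot uniform; biases zero;
  transition matrix zero apart from the mask.
- **Gradients** are computed by hand-written backpropagation in numpy
  (double precision throughout).  The CRF gradient is analytic — marginal
  minus observed counts via the forward–backward recursions — and is
  verified against finite differences in the test suite, as is every other
  parameter tensor via spot checks.

## Numerical choices

- The partition function uses a log-space forward recursion; equivalence
  with literal enumeration over all m^n paths is the tested property
  (≤ 1e-6 on instances up to n = 6, m = 4).
- Start/end handling: transitions *into* start and *out of* end carry a
  fixed mask score of −10⁴ and receive zero gradient; start's outgoing and
  end's incoming rows are learned.
- Viterbi ties break toward the lowest tag index (first argmax), matching
  the enumeration oracle's tie-break.
- Char-CNN max-pooling takes the first maximizing position when tied, and
  its output is invariant to pad symbols beyond the required window.
- An empty corpus cannot be batched; an empty sentence cannot be encoded
  (the CLI passes such sentences through untagged).

## Synthetic data

The generator emulates the structure the model exploits in microbiome
abstracts: sentences of 6–20 tokens from a fixed filler vocabulary with
template POS tags, containing 0–3 bacterial mentions.  Mentions are
pseudo-Latin binomials (capitalized genus built from real bacterial
morphemes + lowercase species epithet), with configurable fractions of
1-token (genus only), 3-token (subspecies) and abbreviated ("X. species")
renderings.  A configurable fraction of mentions (default 30%) is drawn from
a held-back name pool disjoint from the emitted lexicon, so their dictionary
feature reads O and only morphology and context can identify them.  The dict
column is produced by actually running BDMM against the lexicon, never by
copying gold tags.

What this does *not* emulate: real syntactic variety, ambiguous
non-bacterial capitalized tokens (genes, chemicals, place names),
inconsistent tokenization, nested or discontinuous mentions, and the long
tail of real naming (strain designations, serovars).  A perfect score on the
synthetic benchmark therefore demonstrates that the architecture, gradients
and training loop work end to end — that the model can learn both the
gazetteer shortcut and the morphological generalization — not that it
matches published performance on curated PubMed corpora, which requires the
corresponding annotated data.

Default generator sizes for the end-to-end benchmark: 1000 training and 200
validation sentences, one shared lexicon of 100 binomials (20 genera × 5
species), OOV mention rate 0.3.  The benchmark model is reduced — 50-dim
word embeddings and 50 LSTM hidden units, at most 15 epochs — because the
synthetic vocabulary is a few hundred types and saturates well below the
full model's capacity; all other defaults are unchanged.

## Known limitations

- Input must be pre-tokenized; no sentence splitting or tokenizer is
  provided.
- No approximate/fuzzy dictionary matching and no abbreviation expansion
  ("P. gingivalis" only matches a lexicon that contains that surface form).
- Single-threaded CPU training only; the implementation favours
  verifiability (explicit gradients, double precision) over speed and is
  sized for corpora in the tens of thousands of tokens.
- The dictionary and POS embeddings are learned lookups; one-hot encodings
  are a configuration away in spirit but not implemented, as the learned
  form subsumes them.
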