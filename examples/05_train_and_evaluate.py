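"""Training the tagger on synthetic data and evaluating span-level F1.

A small run (300 train / 60 dev sentences, reduced dimensions, 8 epochs)
that finishes in under a minute on one CPU; the full benchmark in
scripts/acceptance.py uses 1000/200 sentences and 15 epochs.
"""

import numpy as np

from bactner import ModelConfig, evaluate_corpus, train
from bactner.corpus import Corpus
from bactner.synthetic import SynthConfig, generate_corpus, generate_lexicon

seed = 7
cfg = SynthConfig(n_sentences=360, oov_entity_rate=0.3, seed=seed)
rng = np.random.default_rng(seed)
lex, names = generate_lexicon(cfg, rng)
corpus = generate_corpus(cfg, lex, rng, names=names)
train_set = Corpus(corpus.sentences[:300], corpus.tag_alphabet)
dev_set = Corpus(corpus.sentences[300:], corpus.tag_alphabet)

config = ModelConfig(word_dim=30, char_dim=15, filter_deep=20, lstm_hidden=30,
                     max_epochs=8, batch_size=16, seed=seed)
model, history = train(train_set, dev_set, config, np.random.default_rng(seed))

for rec in history.records:
    print(f"epoch {rec.epoch:2d}: train loss {rec.train_loss:7.4f}  "
          f"dev F1 {rec.dev_f1:7.3f}  lr {rec.lr:.2e}")
print(f"best epoch: {history.best_epoch}")

report = evaluate_corpus(dev_set, model.predict_corpus(dev_set))
print(report.format())
# The report is strict span-level: an entity counts only when start, end
# and type all match the gold annotation exactly.
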