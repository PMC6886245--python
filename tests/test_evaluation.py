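"""Strict span-level evaluation: exact matching, P/R/F1 arithmetic,
micro-averaging, and an independent conlleval-style cross-check."""

import numpy as np
import pytest

from bactner.corpus import Corpus, EntitySpan, Sentence, Token, spans_to_tags
from bactner.evaluation import (
    EvalCounts,
    evaluate_corpus,
    evaluate_tags,
    match_spans,
    prf,
)


def S(*triples):
    return [EntitySpan(a, b, t) for a, b, t in triples]


class TestMatchSpans:
    def test_identical_lists(self):
        g = S((0, 2, "bacteria"), (3, 5, "bacteria"), (7, 9, "bacteria"))
        c = match_spans(g, list(g))
        assert (c.TP, c.FP, c.FN) == (3, 0, 0)

    def test_empty_predictions(self):
        g = S((0, 2, "bacteria"), (4, 5, "bacteria"))
        c = match_spans(g, [])
        assert (c.TP, c.FP, c.FN) == (0, 0, 2)

    def test_boundary_error_counts_both_ways(self):
        c = match_spans(S((0, 2, "x"), (3, 5, "x")), S((0, 2, "x"), (3, 4, "x")))
        assert (c.TP, c.FP, c.FN) == (1, 1, 1)

    def test_type_mismatch_not_a_hit(self):
        c = match_spans(S((0, 2, "bacteria")), S((0, 2, "gene")))
        assert (c.TP, c.FP, c.FN) == (0, 1, 1)

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            match_spans(S((0, 3, "x"), (2, 4, "x")), [])


class TestPrf:
    # frozen worked examples: printed precision/recall pairs and the F1
    # each must reproduce at three decimals via the harmonic mean
    @pytest.mark.parametrize("p,r,f1", [
        (90.404, 89.007, 89.700),
        (88.476, 81.149, 84.654),
        (89.443, 82.899, 86.047),
        (90.009, 88.300, 89.146),
        (90.502, 88.344, 89.410),
    ])
    def test_harmonic_mean_worked_examples(self, p, r, f1):
        assert round(2 * p * r / (p + r), 3) == f1

    def test_counts_to_percentages(self):
        rep = prf(EvalCounts(TP=3, FP=1, FN=2))
        assert rep.precision == pytest.approx(75.0)
        assert rep.recall == pytest.approx(60.0)
        assert rep.f1 == pytest.approx(2 * 75 * 60 / 135)

    def test_all_zero_convention(self):
        rep = prf(EvalCounts(0, 0, 0))
        assert (rep.precision, rep.recall, rep.f1) == (0.0, 0.0, 0.0)
        assert rep.zero_division

    def test_f1_between_p_and_r(self, rng):
        for _ in range(100):
            c = EvalCounts(*(int(x) for x in rng.integers(0, 20, 3)))
            rep = prf(c)
            if rep.precision + rep.recall > 0:
                assert min(rep.precision, rep.recall) - 1e-9 <= rep.f1
                assert rep.f1 <= max(rep.precision, rep.recall) + 1e-9


class TestEvaluateCorpus:
    def test_gold_vs_gold_is_perfect(self, example_corpus):
        rep = evaluate_corpus(example_corpus, example_corpus)
        assert (rep.precision, rep.recall, rep.f1) == (100.0, 100.0, 100.0)

    def test_all_outside_predictions(self, example_corpus):
        preds = [["O"] * len(s) for s in example_corpus]
        rep = evaluate_corpus(example_corpus, preds)
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.zero_division

    def test_pooled_counts_equal_sentence_sums(self):
        s1 = spans_to_tags(S((0, 2, "x")), 4)
        s2 = spans_to_tags(S((1, 2, "x"), (3, 4, "x")), 5)
        p1 = spans_to_tags(S((0, 2, "x"), (3, 4, "x")), 4)
        p2 = spans_to_tags(S((1, 2, "x")), 5)
        rep = evaluate_tags([s1, s2], [p1, p2])
        c1 = match_spans(S((0, 2, "x")), S((0, 2, "x"), (3, 4, "x")))
        c2 = match_spans(S((1, 2, "x"), (3, 4, "x")), S((1, 2, "x")))
        assert rep.counts.TP == c1.TP + c2.TP
        assert rep.counts.FP == c1.FP + c2.FP
        assert rep.counts.FN == c1.FN + c2.FN

    def test_micro_average_equals_concatenation(self, rng):
        gold, pred = _random_tag_pairs(rng, 20)
        pooled = evaluate_tags(gold, pred)
        concat = evaluate_tags([sum(gold, [])], [sum(pred, [])])
        # concatenating can merge a boundary pair; use offset padding to avoid
        gold_pad = [g + ["O"] for g in gold]
        pred_pad = [p + ["O"] for p in pred]
        concat = evaluate_tags([sum(gold_pad, [])], [sum(pred_pad, [])])
        assert (pooled.counts.TP, pooled.counts.FP, pooled.counts.FN) == (
            concat.counts.TP, concat.counts.FP, concat.counts.FN
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            evaluate_tags([["O", "O"]], [["O"]])


def _random_tag_pairs(rng, n_sent, labels=("bacteria", "gene")):
    gold, pred = [], []
    for _ in range(n_sent):
        n = int(rng.integers(1, 15))
        pair = []
        for _ in range(2):
            tags, prev = [], "O"
            for _ in range(n):
                r = rng.random()
                if prev != "O" and r < 0.3:
                    tags.append("I-" + prev[2:])
                elif r < 0.55:
                    tags.append("B-" + labels[rng.integers(len(labels))])
                else:
                    tags.append("O")
                prev = tags[-1]
            pair.append(tags)
        gold.append(pair[0])
        pred.append(pair[1])
    return gold, pred


def _conlleval_counts(gold, pred):
    """Independent span scorer in the conlleval style: walk the two tag
    sequences in lockstep tracking chunk starts/ends, never building span
    objects."""
    tp = n_gold = n_pred = 0
    for g_tags, p_tags in zip(gold, pred):
        in_correct = False
        g_type = p_type = None
        last_g = last_p = "O"
        for g, p in zip(g_tags + ["O"], p_tags + ["O"]):
            g_start = g.startswith("B-") or (
                g.startswith("I-") and last_g[2:] != g[2:]
            )
            p_start = p.startswith("B-") or (
                p.startswith("I-") and last_p[2:] != p[2:]
            )
            g_end = last_g != "O" and (g == "O" or g_start)
            p_end = last_p != "O" and (p == "O" or p_start)
            if in_correct and g_end and p_end and g_type == p_type:
                tp += 1
                in_correct = False
            elif g_end != p_end:
                in_correct = False
            if g_start and p_start and g[2:] == p[2:]:
                in_correct = True
            n_gold += g_start
            n_pred += p_start
            if g_start:
                g_type = g[2:]
            if p_start:
                p_type = p[2:]
            last_g, last_p = g, p
    return tp, n_pred - tp, n_gold - tp


def test_counts_agree_with_independent_scorer(rng):
    """100 random tag-sequence pairs: identical TP/FP/FN from the span-set
    implementation and a lockstep conlleval-style walk."""
    for _ in range(5):
        gold, pred = _random_tag_pairs(rng, 20)
        # the walk assumes well-formed IOB2 for chunk starts; repair first
        from bactner.corpus import repair_iob2

        gold = [repair_iob2(g) for g in gold]
        pred = [repair_iob2(p) for p in pred]
        rep = evaluate_tags(gold, pred)
        tp, fp, fn = _conlleval_counts(gold, pred)
        assert (rep.counts.TP, rep.counts.FP, rep.counts.FN) == (tp, fp, fn)
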