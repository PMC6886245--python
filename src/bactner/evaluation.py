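"""Strict span-level precision / recall / F1.

An entity counts as correct only on an exact (start, end, type) match —
the CoNLL convention.  Counts are pooled over all sentences
(micro-average) before computing

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R)

with the zero-denominator convention that the metric is 0 (flagged in the
report).  Metrics are percentages, reported at 3 decimals.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .corpus import Corpus, EntitySpan, tags_to_spans

__all__ = ["EvalCounts", "EvalReport", "match_spans", "prf", "evaluate_corpus"]


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    counts: EvalCounts
    per_type: dict[str, "EvalReport"] = field(default_factory=dict)
    zero_division: bool = False

    def format(self) -> str:
        lines = [
            f"{'':12s}{'P':>10s}{'R':>10s}{'F1':>10s}{'TP':>8s}{'FP':>8s}{'FN':>8s}",
            (f"{'overall':12s}{self.precision:10.3f}{self.recall:10.3f}"
             f"{self.f1:10.3f}{self.counts.TP:8d}{self.counts.FP:8d}{self.counts.FN:8d}"),
        ]
        for etype, rep in sorted(self.per_type.items()):
            lines.append(
                f"{etype:12s}{rep.precision:10.3f}{rep.recall:10.3f}"
                f"{rep.f1:10.3f}{rep.counts.TP:8d}{rep.counts.FP:8d}{rep.counts.FN:8d}"
            )
        if self.zero_division:
            lines.append("(zero-denominator convention applied: metric = 0)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "precision": round(self.precision, 3),
            "recall": round(self.recall, 3),
            "f1": round(self.f1, 3),
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
        }


def _check_disjoint(spans: list[EntitySpan], which: str) -> None:
    last_end = -1
    for s in sorted(spans):
        if s.start < last_end:
            raise ValueError(f"overlapping spans in {which} list: {s}")
        last_end = s.end


def match_spans(gold: list[EntitySpan], pred: list[EntitySpan]) -> EvalCounts:
    """Exact-match span counts: TP / FP / FN."""
    _check_disjoint(gold, "gold")
    _check_disjoint(pred, "pred")
    gold_set = set(gold)
    pred_set = set(pred)
    tp = len(gold_set & pred_set)
    return EvalCounts(TP=tp, FP=len(pred_set) - tp, FN=len(gold_set) - tp)


def prf(counts: EvalCounts) -> EvalReport:
    """Precision, recall and harmonic-mean F1 as percentages."""
    zero = False
    if counts.TP + counts.FP > 0:
        p = 100.0 * counts.TP / (counts.TP + counts.FP)
    else:
        p, zero = 0.0, True
    if counts.TP + counts.FN > 0:
        r = 100.0 * counts.TP / (counts.TP + counts.FN)
    else:
        r, zero = 0.0, True
    if p + r > 0:
        f1 = 2.0 * p * r / (p + r)
    else:
        f1, zero = 0.0, True
    return EvalReport(p, r, f1, counts, zero_division=zero)


def evaluate_tags(
    gold_tags: list[list[str]], pred_tags: list[list[str]]
) -> EvalReport:
    """Micro-averaged span evaluation over parallel tag-sequence lists."""
    if len(gold_tags) != len(pred_tags):
        raise ValueError("sentence count mismatch")
    total = EvalCounts()
    by_type: dict[str, EvalCounts] = defaultdict(EvalCounts)
    for g, p in zip(gold_tags, pred_tags):
        if len(g) != len(p):
            raise ValueError("sentence length mismatch")
        gs, ps = tags_to_spans(g), tags_to_spans(p)
        total = total + match_spans(gs, ps)
        types = {s.etype for s in gs} | {s.etype for s in ps}
        for etype in types:
            by_type[etype] = by_type[etype] + match_spans(
                [s for s in gs if s.etype == etype],
                [s for s in ps if s.etype == etype],
            )
    report = prf(total)
    report.per_type = {t: prf(c) for t, c in by_type.items()}
    return report


def evaluate_corpus(gold: Corpus, predicted: "Corpus | list[list[str]]") -> EvalReport:
    """Evaluate predictions (a Corpus or tag-sequence list) against gold tags."""
    gold_tags = [s.gold_tags for s in gold]
    if isinstance(predicted, Corpus):
        pred_tags = [s.gold_tags for s in predicted]
    else:
        pred_tags = predicted
    return evaluate_tags(gold_tags, pred_tags)
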