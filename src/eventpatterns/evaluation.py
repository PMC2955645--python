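"""Event-level scoring with approximate span matching.

A predicted event is credited when its type and Theme agree with a gold event
and its trigger span falls inside the gold trigger span extended by one word
on each side (the slack is configurable).  Matching is greedy, highest score
first, and each gold event can be credited at most once, so
``tp + fn = |gold|`` and ``tp + fp = |predictions|`` always hold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus_io import Document, EventAnnotation

__all__ = ["EvalReport", "approx_span_match", "evaluate", "f1", "tune_threshold"]


@dataclass
class EvalReport:
    """TP/FP/FN counts with derived precision, recall and F1 (fractions).

    Degenerate convention: with zero predictions precision is reported as 0
    and ``degenerate`` is set; F1 is 0 whenever precision and recall are both 0.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    by_type: dict[str, "EvalReport"] = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return self.tp + self.fp == 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        d = {"tp": self.tp, "fp": self.fp, "fn": self.fn,
             "precision": self.precision, "recall": self.recall, "f1": self.f1}
        if self.by_type:
            d["by_type"] = {k: v.as_dict() for k, v in self.by_type.items()}
        return d


_WORD_RE = re.compile(r"\S+")


def _extend_span(text: str, span: tuple[int, int], slack: int) -> tuple[int, int]:
    """Widen ``span`` by up to ``slack`` whitespace-delimited words each side."""
    start, end = span
    if slack:
        words_left = [m for m in _WORD_RE.finditer(text, 0, start)][-slack:]
        if words_left:
            start = words_left[0].start()
        words_right = []
        for m in _WORD_RE.finditer(text, end):
            words_right.append(m)
            if len(words_right) == slack:
                break
        if words_right:
            end = words_right[-1].end()
    return start, end


def approx_span_match(pred: EventAnnotation, gold: EventAnnotation, text: str,
                      slack: int = 1) -> bool:
    """True iff types and Theme agree and the predicted trigger span lies
    within the gold trigger span extended by ``slack`` words per side."""
    if pred.etype != gold.etype or pred.theme != gold.theme:
        return False
    lo, hi = _extend_span(text, gold.trigger.span, slack)
    return lo <= pred.trigger.span[0] and pred.trigger.span[1] <= hi


def evaluate(predictions: dict[str, list[EventAnnotation]], corpus: list[Document],
             slack: int = 1) -> EvalReport:
    """Score predictions against the gold events of ``corpus``.

    Greedy 1-1 matching in descending score order per document; unmatched
    predictions count as FP, unmatched gold events as FN.  The report carries
    a per-event-type breakdown.
    """
    total = EvalReport()

    def bucket(etype: str) -> EvalReport:
        return total.by_type.setdefault(etype, EvalReport())

    for doc in corpus:
        preds = list(predictions.get(doc.doc_id, []))
        preds.sort(key=lambda e: -(e.score if e.score is not None else 0.0))
        unmatched = list(doc.events)
        for p in preds:
            hit = next((g for g in unmatched if approx_span_match(p, g, doc.text, slack)),
                       None)
            if hit is not None:
                unmatched.remove(hit)
                total.tp += 1
                bucket(p.etype).tp += 1
            else:
                total.fp += 1
                bucket(p.etype).fp += 1
        for g in unmatched:
            total.fn += 1
            bucket(g.etype).fn += 1
    return total


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall on whatever scale they share
    (both percentages or both fractions); defined as 0 at (0, 0)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def tune_threshold(ps, corpus: list[Document], annotator, model, grid: list[float],
                   slack: int = 1) -> tuple[float, EvalReport, list[tuple[float, EvalReport]]]:
    """Pick the score threshold maximizing F1 on ``corpus``.

    All candidate matches are collected once at threshold 0; every grid value
    then just re-filters them, so the sweep costs one matching pass.  Ties go
    to the higher threshold (favouring precision).  Returns the winning
    threshold, its report, and the full (threshold, report) curve.
    """
    from .alignment import collect_matches

    if not grid:
        raise ValueError("threshold grid must be non-empty")
    per_doc: dict[str, list] = {}
    for doc in corpus:
        per_doc[doc.doc_id] = collect_matches(ps, doc, annotator, model, threshold=0.0)

    curve: list[tuple[float, EvalReport]] = []
    for t in sorted(grid):
        predictions: dict[str, list[EventAnnotation]] = {}
        for doc_id, matches in per_doc.items():
            best: dict[tuple, EventAnnotation] = {}
            for res in matches:
                if res.norm_score < t:
                    continue
                ev = res.predicted_event
                key = ev.key()
                if key not in best or (ev.score or 0) > (best[key].score or 0):
                    best[key] = ev
            predictions[doc_id] = list(best.values())
        curve.append((t, evaluate(predictions, corpus, slack)))

    best_t, best_rep = curve[0]
    for t, rep in curve[1:]:
        if rep.f1 >= best_rep.f1:  # ties -> higher threshold
            best_t, best_rep = t, rep
    return best_t, best_rep, curve
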