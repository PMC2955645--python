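"""Pattern-set filters: the package's central contribution.

Automatically learned pattern sets are large and noisy; most false positives
come from a small number of identifiable sources.  Four simple, portable
remedies are implemented:

* **trigger-word filter** — rank trigger words by their *hit rate* (fraction
  of corpus occurrences that are annotated triggers of the target event type)
  and keep only patterns anchored on the k best words;
* **length filter** — keep only patterns of at most (or exactly) k tokens,
  countering the alignment's bias towards long patterns;
* **performance filter** — measure each pattern's individual precision on a
  development corpus and keep the k most precise;
* **protein-count partition** — a diagnostic splitting sentences by how many
  protein mentions they contain.

Every filter is a contraction (output patterns are a subset of the input), so
filtering can remove false positives but never adds predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .alignment import SubstitutionModel, collect_matches, predict_corpus
from .corpus_io import AnnotatedSentence, Document, annotate_sentences
from .evaluation import evaluate
from .linguistics import Annotator
from .pattern_extraction import Pattern, PatternSet

__all__ = [
    "TriggerStats", "PatternStats",
    "trigger_hit_rates", "trigger_word_filter",
    "length_filter", "pattern_precision", "per_pattern_stats",
    "performance_filter", "partition_by_protein_count",
]


@dataclass(frozen=True)
class TriggerStats:
    """Corpus statistics for one (case-normalized) trigger word.

    ``hit_rate`` is the number of occurrences annotated as a trigger of the
    target event type divided by the total number of corpus occurrences;
    ``other_or_no_event`` counts the remaining occurrences (including triggers
    of other event types).
    """

    word: str
    event_occurrences: int
    total_occurrences: int

    def __post_init__(self) -> None:
        if self.event_occurrences > self.total_occurrences:
            raise ValueError(f"{self.word}: event occurrences exceed total")

    @property
    def other_or_no_event(self) -> int:
        return self.total_occurrences - self.event_occurrences

    @property
    def hit_rate(self) -> float:
        if self.total_occurrences == 0:
            return 0.0
        return self.event_occurrences / self.total_occurrences


@dataclass(frozen=True)
class PatternStats:
    """Per-pattern performance on an evaluation corpus.

    ``precision`` is ``None`` (undefined) for patterns with zero matches —
    on real corpora a large share of learned patterns never fires on the
    development data.
    """

    pattern_id: str
    matches: int
    tp: int
    fp: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None


def _sorted_stats(stats: list[TriggerStats]) -> list[TriggerStats]:
    # HR descending; ties by total occurrences descending, then lexicographic.
    return sorted(stats, key=lambda s: (-s.hit_rate, -s.total_occurrences, s.word))


def trigger_hit_rates(corpus: list[Document], etype: str,
                      annotator: Annotator) -> list[TriggerStats]:
    """Hit-rate table for every distinct single-word trigger of ``etype``.

    Occurrences are counted over the tokenized corpus, case-insensitive exact
    token match.  Multi-word triggers are excluded (they cannot feed the
    single-token trigger filter).  Sorted hit-rate descending with the
    documented tie-breaks.
    """
    trigger_words: set[str] = set()
    event_counts: dict[str, int] = {}
    for doc in corpus:
        for ev in doc.events:
            w = ev.trigger.surface.lower()
            if len(w.split()) != 1:
                continue
            if ev.etype == etype:
                trigger_words.add(w)
                event_counts[w] = event_counts.get(w, 0) + 1

    totals: dict[str, int] = {w: 0 for w in trigger_words}
    for doc in corpus:
        for sent in annotate_sentences(doc, annotator):
            for tok in sent.tokens:
                w = tok.surface.lower()
                if w in totals:
                    totals[w] += 1

    stats = [
        TriggerStats(w, min(event_counts.get(w, 0), totals[w] or event_counts.get(w, 0)),
                     max(totals[w], event_counts.get(w, 0)))
        for w in trigger_words
    ]
    return _sorted_stats(stats)


def trigger_word_filter(ps: PatternSet, stats: list[TriggerStats], k: int) -> PatternSet:
    """Keep patterns whose trigger word is among the ``k`` best-hit-rate words."""
    if k <= 0:
        raise ValueError("k must be positive")
    keep = {s.word for s in _sorted_stats(stats)[:k]}
    return ps.subset([p for p in ps if p.trigger_word in keep],
                     note=f"trigger_word_filter(k={k})")


def length_filter(ps: PatternSet, max_len: int, exact: bool = False) -> PatternSet:
    """Patterns with at most (or, with ``exact``, exactly) ``max_len`` tokens."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    if exact:
        kept = [p for p in ps if p.length == max_len]
        note = f"length_filter(exact={max_len})"
    else:
        kept = [p for p in ps if p.length <= max_len]
        note = f"length_filter(max_len={max_len})"
    return ps.subset(kept, note=note)


def pattern_precision(pattern: Pattern, dev_corpus: list[Document],
                      annotator: Annotator, model: SubstitutionModel) -> PatternStats:
    """Event-level precision of the singleton pattern set {pattern} on a
    development corpus with gold annotations."""
    singleton = PatternSet(pattern.etype, [pattern])
    preds = predict_corpus(singleton, dev_corpus, annotator, model)
    n_matches = sum(len(v) for v in preds.values())
    rep = evaluate(preds, dev_corpus)
    # FN reflects the whole corpus and is irrelevant for a single pattern.
    return PatternStats(pattern.pattern_id, n_matches, rep.tp, rep.fp)


def per_pattern_stats(ps: PatternSet, dev_corpus: list[Document], annotator: Annotator,
                      model: SubstitutionModel) -> dict[str, PatternStats]:
    """Per-pattern stats for the whole set in one matching pass.

    Equivalent to calling :func:`pattern_precision` per pattern, but the
    corpus is annotated and aligned once with per-pattern attribution.
    """
    from .corpus_io import EventAnnotation

    per_pattern: dict[str, dict[str, list[EventAnnotation]]] = {
        p.pattern_id: {} for p in ps
    }
    for doc in dev_corpus:
        matches = collect_matches(ps, doc, annotator, model, per_pattern=True)
        for res in matches:
            per_pattern[res.pattern_id].setdefault(doc.doc_id, []).append(
                res.predicted_event)
    out: dict[str, PatternStats] = {}
    for p in ps:
        preds = per_pattern[p.pattern_id]
        n_matches = sum(len(v) for v in preds.values())
        rep = evaluate(preds, dev_corpus)
        out[p.pattern_id] = PatternStats(p.pattern_id, n_matches, rep.tp, rep.fp)
    return out


def rank_by_precision(ps: PatternSet, stats: dict[str, PatternStats],
                      drop_undefined: bool = False) -> list[Pattern]:
    """Precision descending; undefined-precision patterns last (or dropped),
    ties by match count descending, then pattern id."""
    def key(p: Pattern):
        s = stats[p.pattern_id]
        prec = s.precision
        return (0 if prec is not None else 1, -(prec or 0.0), -s.matches, p.pattern_id)

    ranked = sorted(ps, key=key)
    if drop_undefined:
        ranked = [p for p in ranked if stats[p.pattern_id].precision is not None]
    return ranked


def performance_filter(ps: PatternSet, dev_corpus: list[Document], annotator: Annotator,
                       model: SubstitutionModel, k: int,
                       drop_undefined: bool = False,
                       stats: dict[str, PatternStats] | None = None) -> PatternSet:
    """Keep the ``k`` individually most precise patterns on the dev corpus."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if stats is None:
        stats = per_pattern_stats(ps, dev_corpus, annotator, model)
    ranked = rank_by_precision(ps, stats, drop_undefined)
    return ps.subset(ranked[:k], note=f"performance_filter(k={k})")


def partition_by_protein_count(corpus: list[Document], k_max: int,
                               annotator: Annotator) -> dict[int, list[AnnotatedSentence]]:
    """Sentences keyed by their exact protein-mention count (1..k_max).

    Sentences with more than ``k_max`` proteins pool into the overflow bucket
    at key ``k_max + 1``.  Partitions are disjoint and jointly cover every
    protein-bearing sentence; protein-free sentences are not returned.
    """
    parts: dict[int, list[AnnotatedSentence]] = {k: [] for k in range(1, k_max + 2)}
    for doc in corpus:
        for sent in annotate_sentences(doc, annotator):
            n = len({e.id for e in sent.entity_tokens.values()})
            if n == 0:
                continue
            parts[min(n, k_max + 1)].append(sent)
    return parts


def export_trigger_stats_tsv(stats: list[TriggerStats], path: str | Path) -> None:
    """TSV with the conventional columns: word, FP, TP, Occurrence, Hit rate."""
    lines = ["word\tFP\tTP\tOccurrence\tHit rate"]
    for s in stats:
        lines.append(f"{s.word}\t{s.other_or_no_event}\t{s.event_occurrences}"
                     f"\t{s.total_occurrences}\t{s.hit_rate:.3f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
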