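"""Multi-layer semi-global alignment of patterns against sentences.

A pattern is matched into a sentence the way a short sequence is aligned into
a longer one: the whole pattern must be accounted for (aligned or deleted at a
gap cost) while sentence overhangs outside the aligned window are free.  The
score of aligning a pattern position to a sentence token is a linear
combination of per-lane substitution scores (token, stem, POS); two special
symbols override the lane lookup:

* the entity placeholder (``PTN``) aligns to any entity-masked sentence token
  at full match score, and
* a registered event-type tag on the pattern's POS lane (e.g. ``GEE``) is a
  wildcard — at prediction time an unseen sentence cannot carry gold trigger
  tags, so the trigger position is constrained through its surface/stem lanes
  only.

Scores are normalized by the pattern's self-score, so a verbatim
re-occurrence of the training core scores exactly 1.0; a threshold on the
normalized score tunes the precision/recall trade-off.  Accepted matches are
turned into predicted events by reading off the entity anchored at the theme
placeholder and the sentence span aligned to the trigger token(s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .corpus_io import (
    DEFAULT_EVENT_TAGS,
    PLACEHOLDER,
    AnnotatedSentence,
    Document,
    EntityMention,
    EventAnnotation,
    annotate_sentences,
    mask_entities,
)
from .linguistics import Annotator
from .pattern_extraction import Pattern, PatternSet

__all__ = ["SubstitutionModel", "MatchResult", "pair_score", "align",
           "match_sentence", "collect_matches", "predict_corpus"]


@dataclass(frozen=True)
class SubstitutionModel:
    """Per-layer substitution scoring, layer weights, gap penalty, threshold.

    Defaults give the token layer the largest weight and the POS layer the
    smallest (token identity is the strongest signal, POS the weakest); each
    layer scores +1 for identity and -1 for a mismatch, optionally overridden
    per symbol pair; gaps cost -0.4 per inserted/deleted token.  Weights are
    non-negative and sum to 1, so the maximal combined score per position is
    the match score and the per-position model is diagonally dominant.
    """

    layer_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_penalty: float = -0.4
    threshold: float = 0.8
    placeholder: str = PLACEHOLDER
    event_tags: tuple[str, ...] = tuple(DEFAULT_EVENT_TAGS.values())
    # optional per-layer explicit overrides: {layer: {(a, b): score}}
    overrides: tuple = ()

    def __post_init__(self) -> None:
        w = self.layer_weights
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("layer weights must be non-negative and sum to 1")
        if self.gap_penalty >= 0:
            raise ValueError("gap penalty must be negative")
        for _, table in self.overrides:
            for (a, b), s in table.items():
                if a == b and s < self.match_score:
                    raise ValueError("override breaks diagonal dominance")

    def _layer_score(self, layer: str, a: str, b: str) -> float:
        for name, table in self.overrides:
            if name == layer and (a, b) in table:
                return table[(a, b)]
        return self.match_score if a == b else self.mismatch_score

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubstitutionModel":
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        overrides = tuple(
            (layer, {(pair.split()[0], pair.split()[1]): float(s)
                     for pair, s in table.items()})
            for layer, table in (cfg.pop("overrides", {}) or {}).items()
        )
        if "layer_weights" in cfg:
            cfg["layer_weights"] = tuple(cfg["layer_weights"])
        if "event_tags" in cfg:
            cfg["event_tags"] = tuple(cfg["event_tags"])
        return cls(overrides=overrides, **cfg)


@dataclass(frozen=True)
class MatchResult:
    pattern_id: str
    doc_id: str
    sent_index: int
    alignment: tuple[tuple[int | None, int | None], ...]
    raw_score: float
    norm_score: float
    predicted_event: EventAnnotation | None = None


def pair_score(pattern: Pattern, p_pos: int, sent: AnnotatedSentence, s_idx: int,
               model: SubstitutionModel) -> float:
    """Combined score for aligning pattern position ``p_pos`` to sentence token
    ``s_idx``: ``w_tok*s_tok + w_stem*s_stem + w_pos*s_pos`` with placeholder
    and trigger-tag overrides."""
    tok = sent.tokens[s_idx]
    if pattern.token_lane[p_pos] == model.placeholder:
        # Placeholder aligns to an entity-masked token at full score.
        if tok.surface == model.placeholder:
            return model.match_score
    wt, ws, wp = model.layer_weights
    s_tok = model._layer_score("token", pattern.token_lane[p_pos], tok.surface)
    s_stem = model._layer_score("stem", pattern.stem_lane[p_pos], tok.stem)
    p_sym = pattern.pos_lane[p_pos]
    if p_sym in model.event_tags:
        s_pos = model.match_score  # trigger tag: wildcard on the POS lane
    else:
        s_pos = model._layer_score("pos", p_sym, tok.pos)
    return wt * s_tok + ws * s_stem + wp * s_pos


def self_score(pattern: Pattern, model: SubstitutionModel) -> float:
    """Score of the pattern aligned to its own core (normalization constant)."""
    wt, ws, wp = model.layer_weights
    total = 0.0
    for i in range(pattern.length):
        if pattern.token_lane[i] == model.placeholder:
            total += model.match_score
            continue
        s_tok = model._layer_score("token", pattern.token_lane[i], pattern.token_lane[i])
        s_stem = model._layer_score("stem", pattern.stem_lane[i], pattern.stem_lane[i])
        s_pos = (model.match_score if pattern.pos_lane[i] in model.event_tags
                 else model._layer_score("pos", pattern.pos_lane[i], pattern.pos_lane[i]))
        total += wt * s_tok + ws * s_stem + wp * s_pos
    return total


def align(pattern: Pattern, sent: AnnotatedSentence, model: SubstitutionModel,
          anchor: tuple[int, int] | None = None) -> MatchResult:
    """Optimal semi-global alignment of the full pattern into the sentence.

    Dynamic programming over monotone alignments: every pattern position is
    either aligned to a sentence token or deleted (gap penalty); sentence
    tokens inside the aligned window that match no pattern position are
    insertions (gap penalty); sentence overhangs before/after the window are
    free.  Ties are broken deterministically: fewer gaps, then leftmost start.

    ``anchor=(p, s)`` constrains pattern position ``p`` to align exactly to
    sentence token ``s`` (used to enumerate candidate theme anchorings).
    """
    m, n = pattern.length, len(sent.tokens)
    if m == 0 or n == 0:
        raise ValueError("pattern and sentence must be non-empty")
    gap = model.gap_penalty
    NEG = float("-inf")

    # cell value: (score, -gaps, -start); parent: (pi, pj, op)
    score = [[NEG] * (n + 1) for _ in range(m + 1)]
    gaps = [[0] * (n + 1) for _ in range(m + 1)]
    start = [[0] * (n + 1) for _ in range(m + 1)]
    parent: list[list[tuple[int, int, str] | None]] = [[None] * (n + 1) for _ in range(m + 1)]

    for j in range(n + 1):
        score[0][j], gaps[0][j], start[0][j] = 0.0, 0, j
    for i in range(1, m + 1):
        if anchor is not None and i - 1 == anchor[0]:
            continue  # the anchored pattern position may not be deleted
        if score[i - 1][0] == NEG:
            continue
        score[i][0] = score[i - 1][0] + gap
        gaps[i][0] = gaps[i - 1][0] + 1
        start[i][0] = 0
        parent[i][0] = (i - 1, 0, "del")

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = (NEG, 0, 0)
            par = None
            # diagonal: consume pattern i-1 against sentence j-1
            if score[i - 1][j - 1] > NEG and (
                anchor is None or i - 1 != anchor[0] or j - 1 == anchor[1]
            ):
                s = score[i - 1][j - 1] + pair_score(pattern, i - 1, sent, j - 1, model)
                st = j - 1 if i == 1 else start[i - 1][j - 1]
                cand = (s, -gaps[i - 1][j - 1], -st)
                if cand > (best[0], -best[1], -best[2]):
                    best = (s, gaps[i - 1][j - 1], st)
                    par = (i - 1, j - 1, "sub")
            # deletion: pattern position i-1 skipped
            if score[i - 1][j] > NEG and not (anchor is not None and i - 1 == anchor[0]):
                s = score[i - 1][j] + gap
                st = j if i == 1 else start[i - 1][j]
                cand = (s, -(gaps[i - 1][j] + 1), -st)
                if cand > (best[0], -best[1], -best[2]):
                    best = (s, gaps[i - 1][j] + 1, st)
                    par = (i - 1, j, "del")
            # insertion: sentence token j-1 unmatched inside the window
            if score[i][j - 1] > NEG:
                s = score[i][j - 1] + gap
                cand = (s, -(gaps[i][j - 1] + 1), -start[i][j - 1])
                if cand > (best[0], -best[1], -best[2]):
                    best = (s, gaps[i][j - 1] + 1, start[i][j - 1])
                    par = (i, j - 1, "ins")
            if par is not None:
                score[i][j], gaps[i][j], start[i][j] = best
                parent[i][j] = par

    # free trailing sentence overhang: best cell in the last row
    best_j, best_key = 0, (NEG, 0, 0)
    for j in range(n + 1):
        if score[m][j] == NEG:
            continue
        key = (score[m][j], -gaps[m][j], -start[m][j])
        if key > best_key:
            best_key, best_j = key, j

    # traceback
    aln: list[tuple[int | None, int | None]] = []
    i, j = m, best_j
    while i > 0:
        par = parent[i][j]
        if par is None:  # in row 0 or start of window
            break
        pi, pj, op = par
        if op == "sub":
            aln.append((i - 1, j - 1))
        elif op == "del":
            aln.append((i - 1, None))
        else:
            aln.append((None, j - 1))
        i, j = pi, pj
    aln.reverse()

    raw = score[m][best_j]
    denom = self_score(pattern, model)
    norm = raw / denom if denom > 0 else 0.0
    return MatchResult(pattern.pattern_id, sent.doc_id, -1, tuple(aln), raw, norm)


def _event_from_match(pattern: Pattern, sent: AnnotatedSentence, res: MatchResult,
                      theme: EntityMention, text: str | None,
                      event_tags: dict[str, str]) -> EventAnnotation | None:
    a2s = {p: s for p, s in res.alignment if p is not None and s is not None}
    trig_cols = [a2s[p] for p in pattern.trigger_positions(event_tags) if p in a2s]
    if not trig_cols:
        return None  # trigger aligned to a gap: no event
    spans = [sent.tokens[c].span for c in trig_cols]
    span = (min(s[0] for s in spans), max(s[1] for s in spans))
    surface = (text[span[0]:span[1]] if text is not None
               else " ".join(sent.tokens[c].surface for c in sorted(trig_cols)))
    trigger = EntityMention(id="", etype=pattern.etype, span=span, surface=surface)
    return EventAnnotation(id="", etype=pattern.etype, trigger=trigger,
                           theme=theme.id, score=res.norm_score)


def match_sentence(ps: PatternSet, sent: AnnotatedSentence, model: SubstitutionModel,
                   text: str | None = None, threshold: float | None = None,
                   event_tags: dict[str, str] = DEFAULT_EVENT_TAGS,
                   sent_index: int = -1, per_pattern: bool = False) -> list[MatchResult]:
    """Match every pattern against an entity-masked sentence.

    For each pattern the aligner is run once per candidate anchoring of the
    theme placeholder (each entity token), keeping the best-scoring anchoring
    per entity.  Results with ``norm_score`` below the threshold, or whose
    trigger aligned to a gap, are rejected; duplicate predicted events keep
    the maximal score.
    """
    thr = model.threshold if threshold is None else threshold
    entity_cols = sorted(sent.entity_tokens)
    best: dict[tuple, MatchResult] = {}
    for pattern in ps:
        for col in entity_cols:
            res = align(pattern, sent, model, anchor=(pattern.theme_pos, col))
            if res.raw_score == float("-inf") or res.norm_score < thr:
                continue
            ev = _event_from_match(pattern, sent, res, sent.entity_tokens[col],
                                   text, event_tags)
            if ev is None:
                continue
            res = replace(res, predicted_event=ev, sent_index=sent_index)
            key = (pattern.pattern_id, *ev.key()) if per_pattern else ev.key()
            if key not in best or res.norm_score > best[key].norm_score:
                best[key] = res
    return sorted(best.values(), key=lambda r: (-r.norm_score, r.pattern_id))


def collect_matches(ps: PatternSet, doc: Document, annotator: Annotator,
                    model: SubstitutionModel, threshold: float | None = None,
                    event_tags: dict[str, str] = DEFAULT_EVENT_TAGS,
                    per_pattern: bool = False) -> list[MatchResult]:
    """Accepted matches over all sentences of a document (prediction mode:
    gold trigger markup, if any, is ignored by masking only entities)."""
    out: list[MatchResult] = []
    for si, sent in enumerate(annotate_sentences(doc, annotator, event_tags)):
        masked = mask_entities(sent, model.placeholder)
        out.extend(match_sentence(ps, masked, model, text=doc.text,
                                  threshold=threshold, event_tags=event_tags,
                                  sent_index=si, per_pattern=per_pattern))
    return out


def predict_corpus(ps: PatternSet, corpus: list[Document], annotator: Annotator,
                   model: SubstitutionModel, threshold: float | None = None,
                   event_tags: dict[str, str] = DEFAULT_EVENT_TAGS,
                   ) -> dict[str, list[EventAnnotation]]:
    """Predicted events per document id (duplicates collapsed, ids assigned)."""
    predictions: dict[str, list[EventAnnotation]] = {}
    for doc in corpus:
        matches = collect_matches(ps, doc, annotator, model, threshold, event_tags)
        seen: dict[tuple, EventAnnotation] = {}
        for res in matches:
            ev = res.predicted_event
            assert ev is not None
            key = ev.key()
            if key not in seen or (ev.score or 0) > (seen[key].score or 0):
                seen[key] = ev
        events = [replace(ev, id=f"E{i}") for i, ev in enumerate(seen.values(), 1)]
        predictions[doc.doc_id] = events
    return predictions
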