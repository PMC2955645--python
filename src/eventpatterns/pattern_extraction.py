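"""Learning three-layer patterns from gold event sentences.

Every gold event yields one *initial pattern*: the sentence is entity-masked,
reduced to its core phrase (the minimal token span containing trigger and
theme plus a configurable neighbourhood), and the three annotation lanes over
that core are recorded — surface tokens, word stems, and POS tags, with the
trigger token's POS replaced by an event-type tag (e.g. ``GEE`` for gene
expression) and entity mentions replaced by the ``PTN`` placeholder on all
lanes.  Duplicates are removed.

Also here: regex pre-tagging of phosphorylation sites ("Ser-473", "tyrosine
705"), which lets the two-slot matcher handle the three-slot phosphorylation
event by attaching the nearest tagged site afterwards.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import (
    DEFAULT_EVENT_TAGS,
    PLACEHOLDER,
    AnnotatedSentence,
    Document,
    EventAnnotation,
    annotate_sentences,
    mask_entities,
)
from .linguistics import Annotator

logger = logging.getLogger(__name__)

__all__ = [
    "Pattern",
    "PatternSet",
    "collect_event_sentences",
    "extract_core_phrase",
    "build_pattern",
    "learn_patterns",
    "tag_phospho_sites",
    "DEFAULT_SITE_REGEXES",
]


@dataclass(frozen=True)
class Pattern:
    """A three-lane pattern over a core phrase.

    All lanes have identical length; ``trigger_pos`` and ``theme_pos`` index
    into them.  The lane symbols at ``theme_pos`` are the entity placeholder.
    Identity (for deduplication) is ``(token_lane, trigger_pos, theme_pos)``:
    orientation matters, so "A activates B" and "B activates A" stay distinct.
    """

    pattern_id: str
    etype: str
    token_lane: tuple[str, ...]
    stem_lane: tuple[str, ...]
    pos_lane: tuple[str, ...]
    trigger_pos: int
    theme_pos: int
    provenance: tuple[str, int] = ("", -1)

    def __post_init__(self) -> None:
        n = len(self.token_lane)
        if not (len(self.stem_lane) == len(self.pos_lane) == n):
            raise ValueError("pattern lanes must have equal length")
        if not (0 <= self.trigger_pos < n and 0 <= self.theme_pos < n):
            raise ValueError("trigger/theme positions out of range")

    @property
    def length(self) -> int:
        return len(self.token_lane)

    def identity(self) -> tuple:
        return (self.token_lane, self.trigger_pos, self.theme_pos)

    def trigger_positions(self, event_tags: dict[str, str] = DEFAULT_EVENT_TAGS) -> list[int]:
        """All lane positions tagged as trigger (multi-token triggers possible)."""
        tags = set(event_tags.values())
        pos = [i for i, p in enumerate(self.pos_lane) if p in tags]
        return pos or [self.trigger_pos]

    @property
    def trigger_word(self) -> str:
        return self.token_lane[self.trigger_pos].lower()


@dataclass
class PatternSet:
    etype: str
    patterns: list[Pattern] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def average_length(self) -> float:
        if not self.patterns:
            return 0.0
        return sum(p.length for p in self.patterns) / len(self.patterns)

    def subset(self, patterns: list[Pattern], note: str = "") -> "PatternSet":
        md = dict(self.metadata)
        if note:
            md.setdefault("filters", []).append(note)
        return PatternSet(self.etype, list(patterns), md)

    # -- TSV serialization (one pattern per line, lanes pipe-joined) --------

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        lines = ["pattern_id\tetype\ttrigger_pos\ttheme_pos\ttoken_lane\tstem_lane\tpos_lane"]
        for p in self.patterns:
            lines.append("\t".join([
                p.pattern_id, p.etype, str(p.trigger_pos), str(p.theme_pos),
                "|".join(p.token_lane), "|".join(p.stem_lane), "|".join(p.pos_lane),
            ]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps({"etype": self.etype, **self.metadata}, indent=2, default=str),
            encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternSet":
        path = Path(path)
        lines = path.read_text(encoding="utf-8").splitlines()
        patterns = []
        etype = ""
        for line in lines[1:]:
            if not line.strip():
                continue
            pid, etype, trg, thm, tok, stm, pos = line.split("\t")
            patterns.append(Pattern(pid, etype, tuple(tok.split("|")),
                                    tuple(stm.split("|")), tuple(pos.split("|")),
                                    int(trg), int(thm)))
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = {}
        if meta_path.exists():
            metadata = json.loads(meta_path.read_text(encoding="utf-8"))
            etype = metadata.pop("etype", etype)
        return cls(etype, patterns, metadata)


def collect_event_sentences(
    corpus: list[Document], etype: str, annotator: Annotator,
) -> list[tuple[AnnotatedSentence, EventAnnotation]]:
    """All (sentence, event) pairs of the requested type across the corpus.

    One pair per event — a sentence describing two events appears twice.
    Cross-sentence events were already dropped during sentence annotation.
    """
    pairs = []
    for doc in corpus:
        for si, sent in enumerate(annotate_sentences(doc, annotator)):
            seen: list[EventAnnotation] = []
            for ev in sent.trigger_tokens.values():
                if ev.etype == etype and ev not in seen:
                    seen.append(ev)
            pairs.extend((sent, ev) for ev in seen)
    return pairs


def extract_core_phrase(sent: AnnotatedSentence, trigger_idx: int, theme_idx: int,
                        neighbourhood: int) -> tuple[int, int]:
    """Inclusive token interval: minimal span over trigger and theme, widened
    by ``neighbourhood`` tokens each side and clipped to the sentence."""
    n = len(sent.tokens)
    if trigger_idx == theme_idx:
        raise ValueError("trigger and theme indices must differ")
    if not (0 <= trigger_idx < n and 0 <= theme_idx < n):
        raise ValueError(f"indices ({trigger_idx}, {theme_idx}) out of range for {n} tokens")
    if neighbourhood < 0:
        raise ValueError("neighbourhood must be non-negative")
    lo = max(0, min(trigger_idx, theme_idx) - neighbourhood)
    hi = min(n - 1, max(trigger_idx, theme_idx) + neighbourhood)
    return lo, hi


def build_pattern(sent: AnnotatedSentence, core: tuple[int, int], trigger_idx: int,
                  theme_idx: int, etype: str,
                  event_tags: dict[str, str] = DEFAULT_EVENT_TAGS,
                  pattern_id: str = "", provenance: tuple[str, int] = ("", -1),
                  trigger_indices: list[int] | None = None) -> Pattern:
    """Materialize the three lanes over ``core`` (inclusive interval).

    POS symbols at trigger positions are replaced by the event-type tag; for
    multi-token triggers every trigger token is tagged and ``trigger_pos``
    records the first.
    """
    lo, hi = core
    if not (lo <= trigger_idx <= hi and lo <= theme_idx <= hi):
        raise ValueError("core must contain trigger and theme")
    trig_set = set(trigger_indices or [trigger_idx])
    toks = sent.tokens[lo:hi + 1]
    tag = event_tags[etype]
    token_lane = tuple(t.surface for t in toks)
    stem_lane = tuple(t.stem for t in toks)
    pos_lane = tuple(tag if lo + i in trig_set else t.pos for i, t in enumerate(toks))
    return Pattern(pattern_id, etype, token_lane, stem_lane, pos_lane,
                   trigger_idx - lo, theme_idx - lo, provenance)


def learn_patterns(corpus: list[Document], etype: str, annotator: Annotator,
                   neighbourhood: int = 1,
                   event_tags: dict[str, str] = DEFAULT_EVENT_TAGS,
                   placeholder: str = PLACEHOLDER) -> PatternSet:
    """Full learning pipeline: collect -> mask -> core -> build -> dedup.

    Deterministic: patterns ordered by provenance then lanes, and invariant
    under permutation of the input documents (up to the deduplicated set).
    """
    if not corpus:
        logger.warning("learn_patterns: empty corpus for %s", etype)
        return PatternSet(etype, [], {"neighbourhood": neighbourhood, "n_docs": 0})

    raw: list[Pattern] = []
    for doc in sorted(corpus, key=lambda d: d.doc_id):
        for si, sent in enumerate(annotate_sentences(doc, annotator, event_tags)):
            masked = mask_entities(sent, placeholder)
            events: list[EventAnnotation] = []
            for ev in masked.trigger_tokens.values():
                if ev.etype == etype and ev not in events:
                    events.append(ev)
            for ev in events:
                trig_idx = sorted(i for i, e in masked.trigger_tokens.items() if e is ev)
                theme_idx = [i for i, m in masked.entity_tokens.items() if m.id == ev.theme]
                if not trig_idx or not theme_idx:
                    continue
                if theme_idx[0] in trig_idx:
                    logger.warning("%s: trigger overlaps theme; event %s skipped",
                                   doc.doc_id, ev.id)
                    continue
                core = extract_core_phrase(masked, trig_idx[0], theme_idx[0], neighbourhood)
                core = (min(core[0], min(trig_idx)), max(core[1], max(trig_idx)))
                raw.append(build_pattern(masked, core, trig_idx[0], theme_idx[0], etype,
                                         event_tags, provenance=(doc.doc_id, si),
                                         trigger_indices=trig_idx))

    raw.sort(key=lambda p: (p.provenance, p.token_lane))
    seen: set[tuple] = set()
    deduped: list[Pattern] = []
    for p in raw:
        key = p.identity()
        if key in seen:
            continue
        seen.add(key)
        deduped.append(Pattern(f"P{len(deduped) + 1:04d}", p.etype, p.token_lane,
                               p.stem_lane, p.pos_lane, p.trigger_pos, p.theme_pos,
                               p.provenance))
    return PatternSet(etype, deduped, {
        "neighbourhood": neighbourhood,
        "n_docs": len(corpus),
        "n_event_instances": len(raw),
    })


#: Default site-mention patterns: residue-position forms like "Ser-473",
#: "Tyr705", "serine 133".
DEFAULT_SITE_REGEXES: tuple[str, ...] = (
    r"\b(?:Ser|Thr|Tyr|His|Asp|Glu|Lys|Arg)-?\d+\b",
    r"\b(?:serine|threonine|tyrosine|histidine)[\s-]?\d+\b",
)


def tag_phospho_sites(text: str, site_regexes: tuple[str, ...] = DEFAULT_SITE_REGEXES,
                      offset: int = 0) -> list[tuple[int, int]]:
    """Character spans of phosphorylation-site mentions, ordered by start.

    ``offset`` shifts spans into document coordinates when ``text`` is a
    sentence slice.  Overlapping hits from different expressions collapse to
    the earliest-longest span.
    """
    spans: list[tuple[int, int]] = []
    for rx in site_regexes:
        for m in re.finditer(rx, text, flags=re.IGNORECASE):
            spans.append((m.start() + offset, m.end() + offset))
    spans.sort(key=lambda s: (s[0], -s[1]))
    out: list[tuple[int, int]] = []
    for s in spans:
        if out and s[0] < out[-1][1]:
            continue
        out.append(s)
    return out
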