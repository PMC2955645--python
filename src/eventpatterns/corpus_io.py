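"""Reading and writing BioNLP'09-style standoff corpora.

A document is a ``.txt`` file with two standoff annotation files referencing
character offsets into it: ``.a1`` holds the given entity mentions (``T``
lines) and ``.a2`` the event annotations (trigger ``T`` lines plus ``E``
lines).  Offsets are 0-based half-open ``[start, end)``.

This module also turns documents into :class:`AnnotatedSentence` objects
(token/stem/POS lanes plus entity and gold-trigger markup) via a pluggable
annotator, and masks entity mentions with a placeholder token so that learned
patterns generalize across protein names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .linguistics import Annotator, Token

logger = logging.getLogger(__name__)

__all__ = [
    "EntityMention",
    "EventAnnotation",
    "Document",
    "AnnotatedSentence",
    "StandoffParseError",
    "StandoffIntegrityError",
    "EVENT_TYPES",
    "DEFAULT_EVENT_TAGS",
    "PLACEHOLDER",
    "read_standoff",
    "write_a2",
    "annotate_sentences",
    "mask_entities",
    "read_corpus_dir",
    "write_corpus_dir",
]

#: Event types handled by default, with the POS-lane tag used for their
#: trigger tokens in gold sentences (configurable; see ``annotate_sentences``).
DEFAULT_EVENT_TAGS: dict[str, str] = {
    "Gene_expression": "GEE",
    "Transcription": "TRN",
    "Protein_catabolism": "CAT",
    "Phosphorylation": "PHO",
}

EVENT_TYPES = tuple(DEFAULT_EVENT_TAGS)

#: Placeholder symbol substituted for entity mentions on all three lanes.
PLACEHOLDER = "PTN"


class StandoffParseError(ValueError):
    """A standoff line does not follow the T/E line grammar."""


class StandoffIntegrityError(ValueError):
    """Annotations are inconsistent with the document text or each other."""


@dataclass(frozen=True)
class EntityMention:
    id: str
    etype: str
    span: tuple[int, int]
    surface: str


@dataclass(frozen=True)
class EventAnnotation:
    """A typed event: trigger expression plus its Theme protein.

    ``theme`` is the id of an :class:`EntityMention`; ``site`` is an optional
    second argument used only for phosphorylation.  ``score`` is attached by
    the matcher on predicted events and is ``None`` on gold ones.
    """

    id: str
    etype: str
    trigger: EntityMention
    theme: str
    site: str | None = None
    score: float | None = None

    def key(self) -> tuple[str, tuple[int, int], str]:
        return (self.etype, self.trigger.span, self.theme)


@dataclass
class Document:
    doc_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)

    def entity_by_id(self, tid: str) -> EntityMention:
        for e in self.entities:
            if e.id == tid:
                return e
        raise KeyError(tid)


@dataclass
class AnnotatedSentence:
    """Tokenized sentence with per-token lanes and entity/trigger markup.

    ``entity_tokens`` maps every token index covered by an entity mention to
    that mention; ``trigger_tokens`` maps trigger token indices to their gold
    event (training corpora only).
    """

    doc_id: str
    sent_span: tuple[int, int]
    tokens: list[Token]
    entity_tokens: dict[int, EntityMention] = field(default_factory=dict)
    trigger_tokens: dict[int, EventAnnotation] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tokens)

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


# ---------------------------------------------------------------------------
# Standoff parsing
# ---------------------------------------------------------------------------

def _parse_t_line(line: str, lineno: int, text: str, fname: str) -> EntityMention:
    parts = line.split("\t")
    if len(parts) < 3:
        raise StandoffParseError(f"{fname}:{lineno}: malformed T line: {line!r}")
    tid, type_span = parts[0], parts[1]
    surface = parts[2]
    bits = type_span.split(" ")
    if len(bits) < 3:
        raise StandoffParseError(f"{fname}:{lineno}: malformed T line: {line!r}")
    etype = bits[0]
    span_field = " ".join(bits[1:])
    if ";" in span_field:
        # Discontinuous trigger: keep the first fragment only.
        logger.warning("%s:%d: discontinuous span; keeping first fragment", fname, lineno)
        span_field = span_field.split(";")[0]
    nums = span_field.split()
    try:
        start, end = int(nums[0]), int(nums[1])
    except (ValueError, IndexError) as exc:
        raise StandoffParseError(f"{fname}:{lineno}: bad span in {line!r}") from exc
    if not (0 <= start < end <= len(text)):
        raise StandoffIntegrityError(
            f"{fname}:{lineno}: span [{start},{end}) outside text of length {len(text)}"
        )
    got = text[start:end]
    # For a discontinuous trigger the stated surface covers all fragments, so
    # only require the first-fragment prefix to agree.
    if got != surface and not surface.startswith(got):
        raise StandoffIntegrityError(
            f"{fname}:{lineno}: surface mismatch: text has {got!r}, annotation says {surface!r}"
        )
    return EntityMention(tid, etype, (start, end), got)


def read_standoff(txt: str, a1: str, a2: str, doc_id: str = "doc",
                  event_types: tuple[str, ...] = EVENT_TYPES) -> Document:
    """Parse a ``.txt`` / ``.a1`` / ``.a2`` triple into a :class:`Document`.

    ``a2`` may be empty (test mode).  Unknown event types and non-T/E lines
    are skipped with a warning; malformed lines raise
    :class:`StandoffParseError`, and annotations that contradict the text
    raise :class:`StandoffIntegrityError`.
    """
    entities: list[EntityMention] = []
    seen: set[str] = set()
    for lineno, line in enumerate(a1.splitlines(), 1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning("a1:%d: skipping non-T line", lineno)
            continue
        ent = _parse_t_line(line, lineno, txt, "a1")
        if ent.id in seen:
            raise StandoffIntegrityError(f"a1:{lineno}: duplicate id {ent.id}")
        seen.add(ent.id)
        entities.append(ent)

    triggers: dict[str, EntityMention] = {}
    events: list[EventAnnotation] = []
    for lineno, line in enumerate(a2.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            trg = _parse_t_line(line, lineno, txt, "a2")
            if trg.id in seen or trg.id in triggers:
                raise StandoffIntegrityError(f"a2:{lineno}: duplicate id {trg.id}")
            triggers[trg.id] = trg
        elif line.startswith("E"):
            parts = line.split("\t")
            if len(parts) < 2:
                raise StandoffParseError(f"a2:{lineno}: malformed E line: {line!r}")
            eid = parts[0]
            args = parts[1].split()
            head = args[0].split(":")
            if len(head) != 2:
                raise StandoffParseError(f"a2:{lineno}: malformed E head: {line!r}")
            etype, tref = head
            if etype not in event_types:
                logger.warning("a2:%d: skipping unknown event type %s", lineno, etype)
                continue
            theme = None
            site = None
            for arg in args[1:]:
                k, _, v = arg.partition(":")
                if k.startswith("Theme") and theme is None:
                    theme = v
                elif k.startswith("Site") and site is None:
                    site = v
            if theme is None:
                raise StandoffParseError(f"a2:{lineno}: event without Theme: {line!r}")
            if tref not in triggers:
                raise StandoffIntegrityError(f"a2:{lineno}: dangling trigger ref {tref}")
            if theme not in seen:
                raise StandoffIntegrityError(f"a2:{lineno}: dangling theme ref {theme}")
            events.append(EventAnnotation(eid, etype, triggers[tref], theme, site=site))
        else:
            logger.warning("a2:%d: skipping unsupported line type %r", lineno, line[:1])
    return Document(doc_id, txt, entities, events)


def write_a2(doc_id: str, predictions: list[EventAnnotation],
             entities: list[EntityMention] | None = None,
             first_trigger_index: int | None = None) -> str:
    """Serialize predicted events as ``.a2`` text (trigger T lines, then E lines).

    Trigger ids continue after the ``.a1`` id space when ``entities`` is given;
    otherwise after the highest numeric id referenced by the predictions.
    Round-trippable by :func:`read_standoff`.
    """
    if not predictions:
        return ""
    if entities is not None:
        ids = {e.id for e in entities}
        for ev in predictions:
            if ev.theme not in ids:
                raise StandoffIntegrityError(
                    f"{doc_id}: prediction {ev.id} has dangling theme {ev.theme}"
                )
    if first_trigger_index is None:
        used = [e.id for e in (entities or [])] + [ev.theme for ev in predictions]
        nums = [int(i[1:]) for i in used if i[:1] == "T" and i[1:].isdigit()]
        first_trigger_index = (max(nums) + 1) if nums else 1

    t_lines: list[str] = []
    e_lines: list[str] = []
    trig_ids: dict[tuple[str, tuple[int, int]], str] = {}
    next_t = first_trigger_index
    for i, ev in enumerate(predictions, 1):
        key = (ev.etype, ev.trigger.span)
        if key not in trig_ids:
            tid = f"T{next_t}"
            next_t += 1
            trig_ids[key] = tid
            t_lines.append(
                f"{tid}\t{ev.etype} {ev.trigger.span[0]} {ev.trigger.span[1]}\t{ev.trigger.surface}"
            )
        line = f"E{i}\t{ev.etype}:{trig_ids[key]} Theme:{ev.theme}"
        if ev.site:
            line += f" Site:{ev.site}"
        e_lines.append(line)
    return "\n".join(t_lines + e_lines) + "\n"


# ---------------------------------------------------------------------------
# Sentence annotation and masking
# ---------------------------------------------------------------------------

def _covering_tokens(tokens: list[Token], span: tuple[int, int]) -> list[int]:
    return [i for i, t in enumerate(tokens)
            if t.span[0] < span[1] and span[0] < t.span[1]]


def annotate_sentences(doc: Document, annotator: Annotator,
                       event_tags: dict[str, str] = DEFAULT_EVENT_TAGS) -> list[AnnotatedSentence]:
    """Segment, tokenize and annotate ``doc``; attach entity and trigger markup.

    Events whose trigger and theme do not fall in the same sentence (the rare
    cross-sentence cases) are dropped with a logged count, never an exception.
    Gold trigger tokens keep their surface and stem but are *not* re-tagged
    here; the event-type POS tag is applied during pattern construction.
    """
    raw = annotator.annotate(doc.text)
    sents = [AnnotatedSentence(doc.doc_id, r.span, list(r.tokens)) for r in raw]

    def locate(span: tuple[int, int]) -> tuple[int, list[int]] | None:
        for si, s in enumerate(sents):
            if s.sent_span[0] <= span[0] and span[1] <= s.sent_span[1]:
                idx = _covering_tokens(s.tokens, span)
                if idx:
                    return si, idx
        return None

    for ent in doc.entities:
        loc = locate(ent.span)
        if loc is None:
            logger.warning("%s: entity %s straddles a sentence boundary; skipped",
                           doc.doc_id, ent.id)
            continue
        si, idx = loc
        for i in idx:
            sents[si].entity_tokens[i] = ent

    dropped = 0
    for ev in doc.events:
        trg = locate(ev.trigger.span)
        thm_ent = next((e for e in doc.entities if e.id == ev.theme), None)
        thm = locate(thm_ent.span) if thm_ent is not None else None
        if trg is None or thm is None or trg[0] != thm[0]:
            dropped += 1
            continue
        si, idx = trg
        for i in idx:
            sents[si].trigger_tokens[i] = ev
    if dropped:
        logger.warning("%s: dropped %d cross-sentence or unlocatable events",
                       doc.doc_id, dropped)
    return sents


def mask_entities(sent: AnnotatedSentence, placeholder: str = PLACEHOLDER) -> AnnotatedSentence:
    """Replace each entity mention's token run by a single placeholder token.

    The placeholder symbol appears on all three lanes.  The returned
    sentence's ``entity_tokens`` maps each placeholder position back to its
    :class:`EntityMention`; other indices are remapped.  Idempotent.
    """
    tokens: list[Token] = []
    entity_tokens: dict[int, EntityMention] = {}
    trigger_tokens: dict[int, EventAnnotation] = {}
    i = 0
    n = len(sent.tokens)
    while i < n:
        ent = sent.entity_tokens.get(i)
        if ent is not None:
            j = i
            while j + 1 < n and sent.entity_tokens.get(j + 1) is ent:
                j += 1
            span = (sent.tokens[i].span[0], sent.tokens[j].span[1])
            new_idx = len(tokens)
            tokens.append(Token(placeholder, placeholder, placeholder, span))
            entity_tokens[new_idx] = ent
            for k in range(i, j + 1):
                if k in sent.trigger_tokens:
                    trigger_tokens[new_idx] = sent.trigger_tokens[k]
            i = j + 1
        else:
            new_idx = len(tokens)
            if i in sent.trigger_tokens:
                trigger_tokens[new_idx] = sent.trigger_tokens[i]
            tokens.append(sent.tokens[i])
            i += 1
    return AnnotatedSentence(sent.doc_id, sent.sent_span, tokens, entity_tokens, trigger_tokens)


# ---------------------------------------------------------------------------
# Corpus directories
# ---------------------------------------------------------------------------

def read_corpus_dir(path: str | Path, event_types: tuple[str, ...] = EVENT_TYPES) -> list[Document]:
    """Read every ``.txt``/``.a1``/``.a2`` triple under ``path`` (by basename)."""
    path = Path(path)
    docs = []
    for txt_file in sorted(path.glob("*.txt")):
        stem = txt_file.stem
        a1_file = path / f"{stem}.a1"
        a2_file = path / f"{stem}.a2"
        a1 = a1_file.read_text(encoding="utf-8") if a1_file.exists() else ""
        a2 = a2_file.read_text(encoding="utf-8") if a2_file.exists() else ""
        docs.append(read_standoff(txt_file.read_text(encoding="utf-8"), a1, a2,
                                  doc_id=stem, event_types=event_types))
    return docs


def write_corpus_dir(corpus: list[Document], path: str | Path) -> None:
    """Write each document as a ``.txt``/``.a1``/``.a2`` triple under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for doc in corpus:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        a1 = "".join(
            f"{e.id}\t{e.etype} {e.span[0]} {e.span[1]}\t{e.surface}\n" for e in doc.entities
        )
        (path / f"{doc.doc_id}.a1").write_text(a1, encoding="utf-8")
        a2_t = []
        a2_e = []
        for ev in doc.events:
            a2_t.append(f"{ev.trigger.id}\t{ev.etype} {ev.trigger.span[0]} "
                        f"{ev.trigger.span[1]}\t{ev.trigger.surface}")
            line = f"{ev.id}\t{ev.etype}:{ev.trigger.id} Theme:{ev.theme}"
            if ev.site:
                line += f" Site:{ev.site}"
            a2_e.append(line)
        a2 = "".join(s + "\n" for s in a2_t + a2_e)
        (path / f"{doc.doc_id}.a2").write_text(a2, encoding="utf-8")
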