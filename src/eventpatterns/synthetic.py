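"""Synthetic standoff corpora with known ground truth.

The generator emits abstracts in the standoff format (text, entity ``.a1``
and event ``.a2`` annotations) built from a closed template/lexicon world, so
every downstream stage — pattern learning, alignment, filtering, evaluation,
split selection — can be tested against planted truths without any external
corpus.

Each sentence is an instance of a template with ``PROTEIN`` and ``TRIGGER``
slots.  Every trigger word carries a target *hit rate*: each of its
occurrences is annotated as a true event with that probability.  Misses of an
*ambiguous* trigger are rendered with the same event-shaped templates but
left unannotated — the planted false-positive source that the trigger and
performance filters are supposed to remove.  Misses of a non-ambiguous
trigger fall into protein-free trigger-distractor sentences, and a configurable
fraction of sentences are plain distractors.

Stems and POS tags for the synthetic vocabulary come from a closed fake
lexicon rather than a real tagger, which keeps test goldens independent of
any annotator implementation.  Generation is byte-deterministic under the
seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .corpus_io import Document, EntityMention, EventAnnotation
from .linguistics import FakeLexiconAnnotator

__all__ = ["Template", "TriggerSpec", "GeneratorConfig", "generate_corpus",
           "corpus_stats", "default_config", "fake_annotator"]


@dataclass(frozen=True)
class Template:
    """A sentence skeleton.  ``kind`` is "event" (1 TRIGGER, >=1 PROTEIN,
    theme = first PROTEIN slot), "trigger_distractor" (TRIGGER, no PROTEIN)
    or "distractor" (neither slot mandatory)."""

    id: str
    tokens: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        n_trig = sum(t == "TRIGGER" for t in self.tokens)
        n_prot = sum(t == "PROTEIN" for t in self.tokens)
        if self.kind == "event" and (n_trig != 1 or n_prot < 1):
            raise ValueError(f"{self.id}: event template needs 1 TRIGGER, >=1 PROTEIN")
        if self.kind == "trigger_distractor" and n_trig != 1:
            raise ValueError(f"{self.id}: trigger_distractor needs exactly 1 TRIGGER")


@dataclass(frozen=True)
class TriggerSpec:
    """A trigger word with its planted hit rate.

    ``ambiguous`` controls what a miss looks like: event-shaped but
    unannotated (ambiguous) versus protein-free (not).  ``templates``
    restricts which event templates the word appears in (``None`` = all);
    concentrating an ambiguous word on few templates guarantees its patterns
    are learned and therefore actually plant false positives.  ``weight``
    scales how often the word is sampled relative to the others.
    """

    word: str
    hit_rate: float
    ambiguous: bool = False
    templates: tuple[str, ...] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_rate <= 1.0:
            raise ValueError(f"{self.word}: hit rate must be in [0, 1]")


DEFAULT_EVENT_TEMPLATES: tuple[Template, ...] = (
    Template("T_e1", ("PROTEIN", "protein", "is", "TRIGGER", "in", "cells", "."), "event"),
    Template("T_e2", ("the", "TRIGGER", "of", "PROTEIN", "was", "evident", "."), "event"),
    Template("T_e3", ("cells", "TRIGGER", "PROTEIN", "during", "activation", "."), "event"),
    Template("T_e4", ("PROTEIN", "gene", "was", "TRIGGER", "after", "treatment", "."), "event"),
    Template("T_e5", ("we", "found", "PROTEIN", "strongly", "TRIGGER", "in", "culture", "."), "event"),
    Template("T_e6", ("analysis", "showed", "TRIGGER", "of", "PROTEIN", "protein", "."), "event"),
)

DEFAULT_OTHER_TEMPLATES: tuple[Template, ...] = (
    Template("T_n1", ("the", "TRIGGER", "assay", "was", "negative", "."), "trigger_distractor"),
    Template("T_n2", ("no", "TRIGGER", "signal", "appeared", "here", "."), "trigger_distractor"),
    Template("T_d1", ("PROTEIN", "binds", "the", "receptor", "complex", "."), "distractor"),
    Template("T_d2", ("the", "cells", "were", "cultured", "overnight", "."), "distractor"),
)

#: Seven unambiguous trigger words, three low-hit-rate words (the dominant
#: planted false-positive source) and one rarer 1:1 ambiguous word; each
#: ambiguous word is pinned to a single event template.
DEFAULT_TRIGGERS: tuple[TriggerSpec, ...] = (
    TriggerSpec("induced", 1.0),
    TriggerSpec("secreted", 1.0),
    TriggerSpec("detected", 1.0),
    TriggerSpec("synthesized", 1.0),
    TriggerSpec("translated", 1.0),
    TriggerSpec("stabilized", 1.0),
    TriggerSpec("degraded", 1.0),
    TriggerSpec("expressed", 0.1, ambiguous=True, templates=("T_e1",)),
    TriggerSpec("produced", 0.1, ambiguous=True, templates=("T_e2",)),
    TriggerSpec("amplified", 0.1, ambiguous=True, templates=("T_e4",)),
    TriggerSpec("released", 0.5, ambiguous=True, templates=("T_e3",), weight=0.5),
)

DEFAULT_PROTEINS: tuple[str, ...] = (
    "CD19", "IL2", "TNF", "STAT3", "FOXP3", "GATA1", "CD28", "IRF4",
)

#: word -> (stem, POS) for the whole synthetic vocabulary, plus the worked
#: example sentence "CD19 protein is expressed".
FAKE_LEXICON: dict[str, tuple[str, str]] = {
    "the": ("the", "DT"), "a": ("a", "DT"), "no": ("no", "DT"),
    "is": ("be", "VBZ"), "was": ("be", "VBD"), "were": ("be", "VBD"),
    "of": ("of", "IN"), "in": ("in", "IN"), "during": ("during", "IN"),
    "after": ("after", "IN"), "we": ("we", "PRP"),
    "protein": ("protein", "NN"), "gene": ("gene", "NN"),
    "cells": ("cell", "NNS"), "cell": ("cell", "NN"),
    "activation": ("activ", "NN"), "treatment": ("treatment", "NN"),
    "culture": ("cultur", "NN"), "analysis": ("analysi", "NN"),
    "assay": ("assay", "NN"), "signal": ("signal", "NN"),
    "receptor": ("receptor", "NN"), "complex": ("complex", "NN"),
    "found": ("find", "VBD"), "showed": ("show", "VBD"),
    "appeared": ("appear", "VBD"), "binds": ("bind", "VBZ"),
    "cultured": ("cultur", "VBN"),
    "strongly": ("strong", "RB"), "markedly": ("marked", "RB"),
    "here": ("here", "RB"), "overnight": ("overnight", "RB"),
    "evident": ("evid", "JJ"), "obvious": ("obviou", "JJ"),
    "negative": ("neg", "JJ"),
    "expressed": ("express", "VBN"), "produced": ("produc", "VBN"),
    "released": ("releas", "VBN"), "induced": ("induc", "VBN"),
    "secreted": ("secret", "VBN"), "detected": ("detect", "VBN"),
    "synthesized": ("synthes", "VBN"), "translated": ("translat", "VBN"),
    "stabilized": ("stabil", "VBN"), "degraded": ("degrad", "VBN"),
    "amplified": ("amplifi", "VBN"),
}

#: Lexical-noise substitutions: same POS, different surface/stem.
NOISE_VARIANTS: dict[str, str] = {
    "strongly": "markedly",
    "evident": "obvious",
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 50
    sentences_per_doc: tuple[int, int] = (4, 7)
    event_type: str = "Gene_expression"
    templates: tuple[Template, ...] = DEFAULT_EVENT_TEMPLATES + DEFAULT_OTHER_TEMPLATES
    trigger_vocab: tuple[TriggerSpec, ...] = DEFAULT_TRIGGERS
    protein_vocab: tuple[str, ...] = DEFAULT_PROTEINS
    distractor_rate: float = 0.25
    noise_rate: float = 0.0
    lexicon: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(FAKE_LEXICON))

    def event_templates(self) -> list[Template]:
        return [t for t in self.templates if t.kind == "event"]

    def trigger_distractor_templates(self) -> list[Template]:
        return [t for t in self.templates if t.kind == "trigger_distractor"]

    def distractor_templates(self) -> list[Template]:
        return [t for t in self.templates if t.kind == "distractor"]


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **overrides)


def noise_free_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study conditions without planted ambiguity: every trigger word has hit
    rate 1.0, so the gold annotation is fully determined by the text and a
    verbatim matcher must recover it exactly."""
    clean = tuple(s for s in DEFAULT_TRIGGERS if s.hit_rate == 1.0)
    return GeneratorConfig(seed=seed, trigger_vocab=clean, **overrides)


def fake_annotator(cfg: GeneratorConfig | None = None) -> FakeLexiconAnnotator:
    """Annotator backed by the generator's lexicon (protein names map to
    themselves so unknown-word fallback is exercised only by design)."""
    lex = dict((cfg.lexicon if cfg else FAKE_LEXICON))
    for name in (cfg.protein_vocab if cfg else DEFAULT_PROTEINS):
        lex.setdefault(name, (name.lower(), "NN"))
    return FakeLexiconAnnotator(lex)


def _render(template: Template, trigger: str | None, rng: random.Random,
            cfg: GeneratorConfig,
            noise_rng: random.Random) -> tuple[list[str], list[int], int | None]:
    """Instantiate a template: returns (tokens, protein token indices,
    trigger token index)."""
    tokens: list[str] = []
    prot_idx: list[int] = []
    trig_idx: int | None = None
    for sym in template.tokens:
        if sym == "PROTEIN":
            prot_idx.append(len(tokens))
            tokens.append(rng.choice(cfg.protein_vocab))
        elif sym == "TRIGGER":
            trig_idx = len(tokens)
            tokens.append(trigger if trigger is not None else "")
        else:
            word = sym
            # separate stream: noise never perturbs the structural draws
            if word in NOISE_VARIANTS and noise_rng.random() < cfg.noise_rate:
                word = NOISE_VARIANTS[word]
            tokens.append(word)
    return tokens, prot_idx, trig_idx


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[Document], dict]:
    """Generate documents with gold annotations and a manifest of planted truth.

    The manifest records, per sentence, the template, trigger word, ambiguity
    class and whether the occurrence was annotated, plus per-trigger
    occurrence/event counts (for checking empirical against target hit rates)
    and the total number of planted events.
    """
    rng = random.Random(cfg.seed)
    noise_rng = random.Random(cfg.seed ^ 0x5EED)
    ev_templates = cfg.event_templates()
    td_templates = cfg.trigger_distractor_templates()
    d_templates = cfg.distractor_templates()
    ev_by_id = {t.id: t for t in ev_templates}

    docs: list[Document] = []
    records: list[dict] = []
    trig_counts = {s.word: {"occurrences": 0, "events": 0} for s in cfg.trigger_vocab}

    for di in range(cfg.n_docs):
        doc_id = f"SYN{di:04d}"
        lo, hi = cfg.sentences_per_doc
        n_sent = rng.randint(lo, hi)
        text_parts: list[str] = []
        entities: list[EntityMention] = []
        events: list[EventAnnotation] = []
        offset = 0
        next_tid = 1
        trigger_lines: list[EntityMention] = []

        for si in range(n_sent):
            spec: TriggerSpec | None = None
            annotated = False
            if d_templates and rng.random() < cfg.distractor_rate:
                template = rng.choice(d_templates)
            else:
                spec = rng.choices(cfg.trigger_vocab,
                                   weights=[s.weight for s in cfg.trigger_vocab])[0]
                hit = rng.random() < spec.hit_rate
                allowed = ([ev_by_id[t] for t in spec.templates]
                           if spec.templates else ev_templates)
                if hit:
                    template = rng.choice(allowed)
                    annotated = True
                elif spec.ambiguous:
                    template = rng.choice(allowed)
                elif td_templates:
                    template = rng.choice(td_templates)
                else:
                    template = rng.choice(allowed)

            tokens, prot_idx, trig_idx = _render(
                template, spec.word if spec else None, rng, cfg, noise_rng)

            spans: list[tuple[int, int]] = []
            for tok in tokens:
                start = offset
                offset += len(tok)
                spans.append((start, offset))
                offset += 1  # joining space (or the gap before next sentence)
            sent_text = " ".join(tokens)
            text_parts.append(sent_text)

            sent_prot_ids: list[str] = []
            for pi in prot_idx:
                ent = EntityMention(f"T{next_tid}", "Protein", spans[pi], tokens[pi])
                next_tid += 1
                entities.append(ent)
                sent_prot_ids.append(ent.id)

            if spec is not None:
                trig_counts[spec.word]["occurrences"] += 1
            if annotated and spec is not None and trig_idx is not None and sent_prot_ids:
                trig_counts[spec.word]["events"] += 1
                trigger = EntityMention("", cfg.event_type, spans[trig_idx],
                                        tokens[trig_idx])
                events.append(EventAnnotation("", cfg.event_type, trigger,
                                              sent_prot_ids[0]))
            records.append({
                "doc_id": doc_id, "sent_index": si, "template_id": template.id,
                "trigger": spec.word if spec else None,
                "ambiguous": bool(spec and spec.ambiguous),
                "annotated": annotated,
            })

        # Assign trigger/event ids after entity ids.
        final_events: list[EventAnnotation] = []
        for i, ev in enumerate(events):
            trig = replace(ev.trigger, id=f"T{next_tid}")
            next_tid += 1
            final_events.append(replace(ev, id=f"E{i + 1}", trigger=trig))
        docs.append(Document(doc_id, " ".join(text_parts), entities, final_events))

    manifest = {
        "seed": cfg.seed,
        "event_type": cfg.event_type,
        "sentences": records,
        "trigger_counts": trig_counts,
        "trigger_specs": [
            {"word": s.word, "hit_rate": s.hit_rate, "ambiguous": s.ambiguous}
            for s in cfg.trigger_vocab
        ],
        "n_events": sum(len(d.events) for d in docs),
    }
    return docs, manifest


def corpus_stats(corpus: list[Document]) -> dict:
    """Summary counts: documents, sentences, tokens, events per type."""
    from .linguistics import split_sentences, tokenize

    events: dict[str, int] = {}
    n_sent = 0
    n_tok = 0
    for doc in corpus:
        n_sent += len(split_sentences(doc.text))
        n_tok += len(tokenize(doc.text))
        for ev in doc.events:
            events[ev.etype] = events.get(ev.etype, 0) + 1
    return {"documents": len(corpus), "sentences": n_sent, "tokens": n_tok,
            "events": dict(sorted(events.items()))}
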