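"""Deterministic linguistic annotation: sentence splitting, tokenization,
stemming and POS tagging.

Patterns are built over three lanes (surface token, word stem, POS tag), so
every corpus has to pass through an annotator before learning or matching.
The annotator is a pluggable contract: any object with an ``annotate(text)``
method returning :class:`RawSentence` objects can be used.  Two annotators
ship with the package:

* :class:`SimpleAnnotator` — a self-contained rule-based annotator (regex
  tokenizer, Porter stems, closed-class lexicon plus suffix heuristics for
  Penn-Treebank-style tags).  Adequate for English biomedical abstracts.
* :class:`FakeLexiconAnnotator` — stems and tags drawn from a closed lexicon.
  Synthetic corpora carry their own lexicon, which makes every golden value in
  the test-suite independent of the rule-based tagger's behaviour.

Both are deterministic: identical input text always yields identical
annotation, a precondition for reproducible pattern learning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol

__all__ = [
    "Token",
    "RawSentence",
    "Annotator",
    "SimpleAnnotator",
    "FakeLexiconAnnotator",
    "porter_stem",
    "tokenize",
    "split_sentences",
]


@dataclass(frozen=True)
class Token:
    """One token with its three annotation lanes and document-level span."""

    surface: str
    stem: str
    pos: str
    span: tuple[int, int]


@dataclass(frozen=True)
class RawSentence:
    span: tuple[int, int]
    tokens: tuple[Token, ...]


class Annotator(Protocol):
    """Contract: deterministic text -> sentences of (surface, stem, POS) tokens."""

    def annotate(self, text: str) -> list[RawSentence]: ...


# Words, hyphen/slash/apostrophe compounds ("Ser-473", "IL-2R"), else single
# non-space characters (punctuation).
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'/][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")

# Sentence break after terminal punctuation followed by whitespace.
_SENT_RE = re.compile(r"[.!?]+(?=\s)|[.!?]+$")


def tokenize(text: str, offset: int = 0) -> list[tuple[str, int, int]]:
    """Tokenize ``text``; spans are shifted by ``offset`` (document coords)."""
    return [(m.group(0), m.start() + offset, m.end() + offset) for m in _TOKEN_RE.finditer(text)]


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences, splitting after terminal punctuation.

    Deliberately eager (splits even before lowercase continuations) so that it
    behaves identically on natural and synthetic text; abbreviation handling is
    not attempted.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_RE.finditer(text):
        end = m.end()
        seg = text[start:end]
        if seg.strip():
            s = start + (len(seg) - len(seg.lstrip()))
            spans.append((s, end))
        start = end
    tail = text[start:]
    if tail.strip():
        s = start + (len(tail) - len(tail.lstrip()))
        spans.append((s, start + len(tail.rstrip())))
    return spans


# ---------------------------------------------------------------------------
# Porter stemmer (Porter 1980), implemented directly from the algorithm.
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_cons(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _double_cons(stem: str) -> bool:
    return len(stem) >= 2 and stem[-1] == stem[-2] and _is_cons(stem, len(stem) - 1)


def _cvc(stem: str) -> bool:
    if len(stem) < 3:
        return False
    return (
        _is_cons(stem, len(stem) - 3)
        and not _is_cons(stem, len(stem) - 2)
        and _is_cons(stem, len(stem) - 1)
        and stem[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    w = word.lower()
    if len(w) <= 2 or not w.isalpha():
        return w

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    flag = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        flag = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        flag = True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _double_cons(w) and not w.endswith(("l", "s", "z")):
            w = w[:-1]
        elif _measure(w) == 1 and _cvc(w):
            w += "e"

    # Step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suf, rep in _STEP2:
        if w.endswith(suf):
            if _measure(w[: -len(suf)]) > 0:
                w = w[: -len(suf)] + rep
            break

    # Step 3
    for suf, rep in _STEP3:
        if w.endswith(suf):
            if _measure(w[: -len(suf)]) > 0:
                w = w[: -len(suf)] + rep
            break

    # Step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 1:
                if suf == "ion" and not stem.endswith(("s", "t")):
                    break
                w = stem
            break

    # Step 5a
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _cvc(w[:-1])):
            w = w[:-1]

    # Step 5b
    if _measure(w) > 1 and _double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# POS tagging
# ---------------------------------------------------------------------------

# Closed-class lexicon (Penn Treebank tags) with irregular lemmas.
_LEXICON: dict[str, tuple[str, str]] = {
    "the": ("the", "DT"), "a": ("a", "DT"), "an": ("an", "DT"),
    "this": ("this", "DT"), "these": ("these", "DT"), "that": ("that", "IN"),
    "is": ("be", "VBZ"), "are": ("be", "VBP"), "was": ("be", "VBD"),
    "were": ("be", "VBD"), "be": ("be", "VB"), "been": ("be", "VBN"),
    "being": ("be", "VBG"), "has": ("have", "VBZ"), "have": ("have", "VBP"),
    "had": ("have", "VBD"), "of": ("of", "IN"), "in": ("in", "IN"),
    "by": ("by", "IN"), "at": ("at", "IN"), "on": ("on", "IN"),
    "to": ("to", "TO"), "and": ("and", "CC"), "or": ("or", "CC"),
    "but": ("but", "CC"), "not": ("not", "RB"), "no": ("no", "DT"),
    "with": ("with", "IN"), "for": ("for", "IN"), "as": ("as", "IN"),
    "from": ("from", "IN"), "during": ("during", "IN"), "after": ("after", "IN"),
    "we": ("we", "PRP"), "it": ("it", "PRP"), "which": ("which", "WDT"),
    "can": ("can", "MD"), "may": ("may", "MD"), "could": ("could", "MD"),
}

_PUNCT_TAGS = {".": ".", ",": ",", ";": ":", ":": ":", "?": ".", "!": ".",
               "(": "(", ")": ")", '"': "''", "'": "''", "%": "NN"}


def _rule_pos(word: str) -> str:
    if word in _PUNCT_TAGS:
        return _PUNCT_TAGS[word]
    if not any(c.isalpha() for c in word):
        return "CD"
    lw = word.lower()
    if lw.endswith("ed"):
        return "VBN"
    if lw.endswith("ing"):
        return "VBG"
    if lw.endswith("ly"):
        return "RB"
    if lw.endswith(("ion", "ment", "ness", "ity", "ase", "or")):
        return "NN"
    if lw.endswith("s") and not lw.endswith("ss") and len(lw) > 3:
        return "NNS"
    if lw.endswith(("al", "ous", "ive", "ic", "able")):
        return "JJ"
    return "NN"


class SimpleAnnotator:
    """Rule-based annotator: regex tokenizer, Porter stems, heuristic tags."""

    def annotate(self, text: str) -> list[RawSentence]:
        out = []
        for s, e in split_sentences(text):
            toks = []
            for surf, ts, te in tokenize(text[s:e], offset=s):
                lw = surf.lower()
                if lw in _LEXICON:
                    stem, pos = _LEXICON[lw]
                else:
                    stem, pos = porter_stem(lw), _rule_pos(surf)
                toks.append(Token(surf, stem, pos, (ts, te)))
            if toks:
                out.append(RawSentence((s, e), tuple(toks)))
        return out


class FakeLexiconAnnotator:
    """Annotator whose stems/tags come from a closed ``word -> (stem, pos)`` map.

    Unknown words fall back to ``(lowercased surface, "NN")`` and punctuation
    to its literal tag, so annotation never fails; but corpora generated with a
    matching lexicon are covered exactly.
    """

    def __init__(self, lexicon: dict[str, tuple[str, str]]):
        self.lexicon = dict(lexicon)

    def annotate(self, text: str) -> list[RawSentence]:
        out = []
        for s, e in split_sentences(text):
            toks = []
            for surf, ts, te in tokenize(text[s:e], offset=s):
                entry = self.lexicon.get(surf) or self.lexicon.get(surf.lower())
                if entry is not None:
                    stem, pos = entry
                elif surf in _PUNCT_TAGS:
                    stem, pos = surf, _PUNCT_TAGS[surf]
                else:
                    stem, pos = surf.lower(), "NN"
                toks.append(Token(surf, stem, pos, (ts, te)))
            if toks:
                out.append(RawSentence((s, e), tuple(toks)))
        return out
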