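import random

import pytest

from eventpatterns.alignment import (
    SubstitutionModel,
    align,
    match_sentence,
    pair_score,
    predict_corpus,
)
from eventpatterns.corpus_io import AnnotatedSentence, annotate_sentences, mask_entities, read_standoff
from eventpatterns.linguistics import Token
from eventpatterns.pattern_extraction import Pattern, PatternSet, learn_patterns
from eventpatterns.synthetic import fake_annotator, generate_corpus, noise_free_config


def make_sentence(rows, doc_id="d"):
    """rows: list of (surface, stem, pos) triples."""
    toks = [Token(s, st, p, (i * 2, i * 2 + 1)) for i, (s, st, p) in enumerate(rows)]
    return AnnotatedSentence(doc_id, (0, len(rows) * 2), toks)


def brute_force_score(pattern, sent, model):
    """Exhaustive enumeration over all monotone alignments of the full pattern
    into the sentence (free sentence overhangs, penalized interior gaps)."""
    m, n = pattern.length, len(sent.tokens)
    best = float("-inf")

    def rec(i, prev, score):
        nonlocal best
        if i == m:
            best = max(best, score)
            return
        rec(i + 1, prev, score + model.gap_penalty)  # pattern position deleted
        for j in range((prev + 1) if prev is not None else 0, n):
            ins = (j - prev - 1) if prev is not None else 0
            rec(i + 1, j, score + ins * model.gap_penalty
                + pair_score(pattern, i, sent, j, model))

    rec(0, None, 0.0)
    return best


class TestPairScore:
    def test_identical_symbols_maximal(self, model):
        p = Pattern("P", "Gene_expression", ("a",), ("x",), ("N",), 0, 0)
        sent = make_sentence([("a", "x", "N")])
        assert pair_score(p, 0, sent, 0, model) == pytest.approx(model.match_score)

    def test_token_mismatch_stem_and_pos_match(self, model):
        # "expressed" vs "expressing": stems agree, here POS set equal too;
        # combined score = -w_tok + w_stem + w_pos = 0 under the defaults.
        p = Pattern("P", "Gene_expression", ("expressed",), ("express",), ("VBN",), 0, 0)
        sent = make_sentence([("expressing", "express", "VBN")])
        got = pair_score(p, 0, sent, 0, model)
        assert got == pytest.approx(-0.5 + 0.3 + 0.2)
        assert model.mismatch_score < got < model.match_score

    def test_placeholder_vs_entity_token_full_match(self, model):
        p = Pattern("P", "Gene_expression", ("PTN", "x"), ("PTN", "x"), ("PTN", "N"), 1, 0)
        sent = make_sentence([("PTN", "PTN", "PTN")])
        assert pair_score(p, 0, sent, 0, model) == pytest.approx(model.match_score)

    def test_event_tag_wildcard_on_pos_lane(self, model):
        p = Pattern("P", "Gene_expression", ("expressed",), ("express",), ("GEE",), 0, 0)
        sent = make_sentence([("expressed", "express", "VBN")])
        assert pair_score(p, 0, sent, 0, model) == pytest.approx(model.match_score)


class TestModelValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SubstitutionModel(layer_weights=(0.5, 0.5, 0.5))

    def test_gap_penalty_must_be_negative(self):
        with pytest.raises(ValueError):
            SubstitutionModel(gap_penalty=0.1)


class TestAlign:
    def test_self_match_normalizes_to_one(self, model):
        p = Pattern("P", "Gene_expression",
                    ("PTN", "protein", "is", "expressed"),
                    ("PTN", "protein", "be", "express"),
                    ("PTN", "NN", "VBZ", "GEE"), 3, 0)
        sent = make_sentence([("PTN", "PTN", "PTN"), ("protein", "protein", "NN"),
                              ("is", "be", "VBZ"), ("expressed", "express", "VBN")])
        res = align(p, sent, model)
        assert res.norm_score == pytest.approx(1.0)

    def test_single_pattern_deletion_hand_computed(self, model):
        # sentence lacks "protein": best alignment deletes that position;
        # raw = self_score - match(protein) + gap = 4 - 1 - 0.4 = 2.6
        p = Pattern("P", "Gene_expression",
                    ("PTN", "protein", "is", "expressed"),
                    ("PTN", "protein", "be", "express"),
                    ("PTN", "NN", "VBZ", "GEE"), 3, 0)
        sent = make_sentence([("PTN", "PTN", "PTN"), ("is", "be", "VBZ"),
                              ("expressed", "express", "VBN")])
        res = align(p, sent, model)
        assert res.raw_score == pytest.approx(2.6)
        assert res.norm_score == pytest.approx(2.6 / 4.0)

    def test_free_sentence_overhangs(self, model):
        p = Pattern("P", "Gene_expression", ("a",), ("a",), ("A",), 0, 0)
        sent = make_sentence([("x", "x", "X"), ("a", "a", "A"), ("y", "y", "Y")])
        res = align(p, sent, model)
        assert res.raw_score == pytest.approx(model.match_score)
        assert res.alignment == ((0, 1),)

    def test_deterministic_and_leftmost_on_ties(self, model):
        p = Pattern("P", "Gene_expression", ("a",), ("a",), ("A",), 0, 0)
        sent = make_sentence([("a", "a", "A"), ("a", "a", "A")])
        first = align(p, sent, model)
        second = align(p, sent, model)
        assert first == second
        assert first.alignment == ((0, 0),)

    def test_matches_brute_force_on_random_instances(self, model):
        """DP optimality against exhaustive enumeration (small instances)."""
        rng = random.Random(7)
        alpha = "abcde"

        def lane(k):
            return tuple(rng.choice(alpha) for _ in range(k))

        for _ in range(300):
            m, n = rng.randint(1, 4), rng.randint(1, 6)
            p = Pattern("P", "Gene_expression", lane(m), lane(m), lane(m),
                        rng.randrange(m), rng.randrange(m))
            sent = make_sentence([(rng.choice(alpha),) * 3 for _ in range(n)])
            assert align(p, sent, model).raw_score == pytest.approx(
                brute_force_score(p, sent, model))


class TestMatchSentence:
    def _worked_setup(self, annotator):
        txt = "CD19 protein is expressed"
        doc = read_standoff(txt, "T1\tProtein 0 4\tCD19", "")
        sent = mask_entities(annotate_sentences(doc, annotator)[0])
        p = Pattern("P1", "Gene_expression",
                    ("PTN", "protein", "is", "expressed"),
                    ("PTN", "protein", "be", "express"),
                    ("PTN", "NN", "VBZ", "GEE"), 3, 0)
        return doc, sent, PatternSet("Gene_expression", [p])

    def test_verbatim_reoccurrence_fires_at_threshold_one(self, annotator, exact_model):
        doc, sent, ps = self._worked_setup(annotator)
        results = match_sentence(ps, sent, exact_model, text=doc.text)
        assert len(results) == 1
        ev = results[0].predicted_event
        assert ev.trigger.span == (16, 25)
        assert ev.theme == "T1"

    def test_two_entities_yield_two_candidate_anchorings(self, annotator, model):
        txt = "CD19 near IL2 protein is expressed"
        a1 = "T1\tProtein 0 4\tCD19\nT2\tProtein 10 13\tIL2\n"
        doc = read_standoff(txt, a1, "")
        sent = mask_entities(annotate_sentences(doc, annotator)[0])
        _, _, ps = self._worked_setup(annotator)
        results = match_sentence(ps, sent, model, text=doc.text, threshold=-1.0)
        themes = {r.predicted_event.theme for r in results}
        assert themes == {"T1", "T2"}
        best = {r.predicted_event.theme: r.norm_score for r in results}
        # the adjacent protein wins: its anchoring needs no interior gaps
        assert best["T2"] == pytest.approx(1.0)
        assert best["T2"] > best["T1"]

    def test_threshold_zero_is_recall_ceiling(self, annotator, model):
        doc, sent, ps = self._worked_setup(annotator)
        lo = match_sentence(ps, sent, model, text=doc.text, threshold=0.0)
        hi = match_sentence(ps, sent, model, text=doc.text, threshold=1.0)
        lo_keys = {r.predicted_event.key() for r in lo}
        hi_keys = {r.predicted_event.key() for r in hi}
        assert hi_keys <= lo_keys


class TestPredictCorpus:
    def test_empty_pattern_set(self, annotator, model, synthetic_corpus):
        _, corpus, _ = synthetic_corpus
        preds = predict_corpus(PatternSet("Gene_expression", []), corpus[:3],
                               annotator, model)
        assert all(not v for v in preds.values())

    def test_noise_free_corpus_reproduces_gold_exactly(self, exact_model):
        cfg = noise_free_config(seed=11, n_docs=20)
        corpus, _ = generate_corpus(cfg)
        ann = fake_annotator(cfg)
        ps = learn_patterns(corpus, "Gene_expression", ann)
        preds = predict_corpus(ps, corpus, ann, exact_model)
        for doc in corpus:
            got = {e.key() for e in preds[doc.doc_id]}
            want = {e.key() for e in doc.events}
            assert got == want

    def test_byte_stable_across_runs(self, exact_model):
        cfg = noise_free_config(seed=11, n_docs=5)
        corpus, _ = generate_corpus(cfg)
        ann = fake_annotator(cfg)
        ps = learn_patterns(corpus, "Gene_expression", ann)
        a = predict_corpus(ps, corpus, ann, exact_model)
        b = predict_corpus(ps, corpus, ann, exact_model)
        assert a == b
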