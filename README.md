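# eventpatterns

Pattern-based extraction of molecular events — gene expression,
transcription, protein catabolism, phosphorylation — from biomedical
abstracts with pre-annotated protein mentions (BioNLP'09-style standoff
corpora), built around a simple observation: automatically learned pattern
sets are large and noisy, and *filtering* them with cheap, portable criteria
trades a small recall loss for a large precision gain.

## Who this is for

Text-mining practitioners who work with automatically learned linguistic
patterns and need a principled way to prune them, and anyone who wants a
self-contained, testable re-implementation of the classic
three-layer-pattern / multi-layer-alignment extraction pipeline with its
filtering techniques.

## The method in brief

Every gold event yields an initial **pattern**: the entity-masked sentence
reduced to its core phrase (minimal span over trigger and Theme plus a
neighbourhood), stored as three aligned lanes — tokens, stems, POS tags —
with the entity placeholder `PTN` and an event-type tag (e.g. `GEE`) at the
trigger position:

| lane  |       |         |     |           |
|-------|-------|---------|-----|-----------|
| token | PTN   | protein | is  | expressed |
| stem  | PTN   | protein | be  | express   |
| POS   | PTN   | NN      | VBZ | GEE       |

Patterns are matched into sentences by semi-global alignment where each
position's score is a weighted combination of per-lane substitution scores
(weights w = (0.5, 0.3, 0.2), match +1 / mismatch −1 per lane, gap −0.4),
normalized by the pattern self-score; a threshold t on the normalized score
trades precision against recall. Predictions are scored at event level with
approximate span matching: P = tp/(tp+fp), R = tp/(tp+fn),
F1 = 2PR/(P+R).

The package's centre of gravity is the **filters**:

* *trigger hit rate* — HR(w) = (occurrences of w annotated as a trigger of
  the target type) / (all occurrences of w); keep patterns of the k
  best-HR trigger words;
* *pattern length* — keep patterns of at most k tokens;
* *pattern performance* — keep the k patterns with the best individual
  precision on a development corpus;
* *resampled selection* — optimize filters on several random train/dev
  splits and take the union of the per-split winners, ranked by development
  precision, for use on held-out data.

A synthetic standoff-corpus generator with planted trigger hit rates and
ambiguity classes makes every stage testable against known ground truth; no
external corpus is required (the real BioNLP'09 corpus remains a drop-in
input).

## Worked example

Generate a 50-document synthetic corpus, learn patterns, predict at the
exact-match threshold, evaluate, then apply the trigger-word filter:

```
$ evpat synth --seed 1 --n-docs 50 --out corpus
wrote 50 documents, 138 events to corpus

$ evpat learn --corpus corpus --fake-lexicon --out patterns.tsv
43 patterns (average length 4.81) -> patterns.tsv

$ evpat predict --patterns patterns.tsv --corpus corpus --threshold 1.0 \
      --fake-lexicon --out pred
187 predicted events -> pred

$ evpat evaluate --pred pred --gold corpus
{ "tp": 138, "fp": 49, "fn": 0,
  "precision": 0.738, "recall": 1.000, "f1": 0.849, ... }

$ evpat filter --patterns patterns.tsv --trigger-k 7 --dev corpus \
      --fake-lexicon --out filtered.tsv
40 patterns -> filtered.tsv

$ evpat predict --patterns filtered.tsv --corpus corpus --threshold 1.0 \
      --fake-lexicon --out pred2
130 predicted events -> pred2

$ evpat evaluate --pred pred2 --gold corpus
{ "tp": 130, "fp": 0, "fn": 8,
  "precision": 1.000, "recall": 0.942, "f1": 0.970, ... }
```

Reading: the unfiltered pattern set finds every planted event (recall 1.0)
but one prediction in four is false (precision 0.738) — the generator plants
trigger words that are only sometimes annotated as events. Keeping only the
seven most reliable trigger words removes all 49 false positives at the cost
of 8 of 138 true events: precision 0.738 → 1.000, recall 1.000 → 0.942. That
asymmetry — large precision gain, small recall cost — is the package's whole
point. Filters can only remove predictions (they are contractions on the
pattern set), so recall never increases; the trick is choosing filters whose
removals are almost all false positives.

The `--fake-lexicon` flag selects the closed-lexicon annotator matching the
synthetic vocabulary; on real text, omit it to use the built-in rule-based
annotator (Porter stems, lexicon+suffix POS tags), or plug in your own via
the library API.

Further subcommands: `evpat tune` (threshold selection on a development
corpus), `evpat select` (resampled split optimization and pattern-set
union). See `docs/methods.md` for the model, the filter definitions, the
generator's study conditions, and known limitations.

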