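"""Published reference values for the BioNLP'09 gene-expression task.

These small tables ship with the package as worked-example inputs: the
trigger-word counts observed on the shared-task training data and the
precision/recall of the filter configurations evaluated on its development
data.  They let the hit-rate formula and the F1 computation be exercised
against independently printed numbers without downloading the corpus.

Two trigger rows are known to be internally inconsistent in the published
table ("express" and "overexpression": the stated hit rate does not equal
TP/Occurrence at one-decimal rounding); the package computes the formula and
leaves the printed value as-is for comparison.
"""

from __future__ import annotations

__all__ = ["GENE_EXPRESSION_TRIGGERS", "FILTER_RESULTS",
           "INCONSISTENT_TRIGGER_ROWS", "TEST_SET_RESULTS"]

#: (word, FP, TP, occurrence, printed hit rate) for the gene-expression
#: event on the training data, hit-rate descending.
GENE_EXPRESSION_TRIGGERS: tuple[tuple[str, int, int, int, float], ...] = (
    ("co-expression", 0, 2, 3, 0.7),
    ("coexpressed", 0, 4, 6, 0.7),
    ("nonexpressing", 0, 2, 3, 0.7),
    ("expressing", 1, 44, 75, 0.6),
    ("expressed", 25, 136, 232, 0.6),
    ("express", 15, 43, 81, 0.6),
    ("production", 6, 150, 298, 0.5),
    ("co-transfections", 1, 1, 2, 0.5),
    ("resynthesized", 0, 1, 2, 0.5),
    ("expression", 106, 873, 1768, 0.5),
    ("produce", 2, 16, 33, 0.5),
    ("expresses", 0, 4, 9, 0.4),
    ("produces", 0, 2, 5, 0.4),
    ("overexpression", 53, 27, 80, 0.4),
)

#: Rows whose printed hit rate disagrees with TP/Occurrence at one decimal.
INCONSISTENT_TRIGGER_ROWS: tuple[str, ...] = ("express", "overexpression")

#: Filter rows whose printed F1 differs from 2PR/(P+R) by more than 0.1
#: (presumably computed from unrounded precision/recall).
F1_NEAR_MISS_ROWS: tuple[str, ...] = ("performance_top_50",)

#: (label, precision %, recall %, printed F1 %) for gene-expression event
#: extraction on the development data under different filter combinations.
FILTER_RESULTS: tuple[tuple[str, float, float, float], ...] = (
    ("no_filter", 24.7, 49.2, 32.9),
    ("trigger_word", 39.7, 48.0, 43.5),
    ("length_exactly_4", 51.0, 29.8, 37.6),
    ("length_max_4", 56.2, 43.5, 49.0),
    ("performance_top_50", 50.0, 48.3, 49.0),
    ("trigger_word_plus_length", 65.6, 39.3, 49.2),
    ("trigger_word_plus_performance", 77.4, 46.3, 58.0),
)

#: (label, precision %, recall %, printed F1 %) on the held-back test data:
#: the unfiltered baseline and the union of the five per-split optimized sets.
TEST_SET_RESULTS: tuple[tuple[str, float, float, float], ...] = (
    ("baseline", 17.2, 43.9, 24.8),
    ("union_of_104_patterns", 58.2, 46.8, 51.9),
)
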