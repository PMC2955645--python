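import pytest

from eventpatterns.alignment import SubstitutionModel
from eventpatterns.corpus_io import read_standoff
from eventpatterns.synthetic import default_config, fake_annotator, generate_corpus

# Worked example: "CD19 protein is expressed" with one gene-expression event.
TABLE_TXT = "CD19 protein is expressed"
TABLE_A1 = "T1\tProtein 0 4\tCD19\n"
TABLE_A2 = ("T2\tGene_expression 16 25\texpressed\n"
            "E1\tGene_expression:T2 Theme:T1\n")


@pytest.fixture(scope="session")
def worked_doc():
    return read_standoff(TABLE_TXT, TABLE_A1, TABLE_A2, doc_id="worked")


@pytest.fixture(scope="session")
def annotator():
    return fake_annotator()


@pytest.fixture(scope="session")
def model():
    return SubstitutionModel()


@pytest.fixture(scope="session")
def exact_model():
    """Threshold 1.0: only verbatim re-occurrences of training cores fire."""
    return SubstitutionModel(threshold=1.0)


@pytest.fixture(scope="session")
def synthetic_corpus():
    """Default study-condition corpus (50 docs, planted ambiguous triggers)."""
    cfg = default_config(seed=1)
    corpus, manifest = generate_corpus(cfg)
    return cfg, corpus, manifest
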