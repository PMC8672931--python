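import pytest

from litgraph import synthesize as sy
from litgraph.corpus import Corpus, Document


@pytest.fixture(scope="session")
def fixture_corpus():
    """The small fixed 20-document corpus with planted phrases."""
    corpus, truth = sy.generate_corpus(sy.fixture_config())
    return corpus, truth


@pytest.fixture(scope="session")
def study_corpus():
    """The 200-document corpus used for retrieval-recovery checks.

    Each planted phrase targets exactly one document so phrase queries have a
    unique best answer.
    """
    config = sy.GeneratorConfig(
        n_docs=200,
        vocab_size=500,
        planted_terms=[
            sy.PlantedTerm("viral spike protein", (0,), freq=4),
            sy.PlantedTerm("community transmission chain", (57,), freq=4),
            sy.PlantedTerm("intensive care admission", (112,), freq=3),
            sy.PlantedTerm("antibody neutralization assay", (163,), freq=4),
            sy.PlantedTerm("household contact tracing", (199,), freq=3),
        ],
        citation_density=3.0,
        year_range=(2000, 2021),
        seed=7,
    )
    corpus, truth = sy.generate_corpus(config)
    return config, corpus, truth


def tiny_corpus(docs, mentions=()):
    """Hand-built corpus from (doc_id, year) or Document entries."""
    corpus = Corpus()
    for entry in docs:
        if isinstance(entry, Document):
            corpus.add(entry)
        else:
            doc_id, year = entry
            corpus.add(Document(doc_id=doc_id, year=year))
    corpus.mentions = list(mentions)
    return corpus
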