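"""Deterministic synthetic corpora with planted terms, citations and qrels.

The generator emulates the statistical structure the rest of the toolkit
assumes about a CORD-19-style collection, without any external download:

* filler text drawn from a synthetic vocabulary with a Zipf-like frequency
  profile (so idf discrimination between tokens is non-trivial);
* user-specified multi-word phrases planted at controlled frequencies in
  chosen documents, each occurrence as its own sentence so every indexing
  scheme (full text, title+abstract, paragraph, first/last sentence) can see
  it — the first occurrence lands at the end of a body paragraph, the second
  in the abstract, further ones at paragraph boundaries;
* citations sampled only toward same-year-or-older documents (the citation
  graph restricted to strictly older targets is acyclic), with section
  labels drawn from a configurable distribution;
* graded relevance judgments derived from the generated text: documents
  containing a query's phrase verbatim get grade 2, documents containing at
  least half of the query's tokens get grade 1, the rest grade 0.

Everything is a pure function of the config (including the seed); the same
config yields byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    Corpus,
    CitationMention,
    Document,
    normalize_section,
    write_fulltext_json,
    write_metadata_jsonl,
)
from .ir_eval import Qrels
from .terms import tokenize

DEFAULT_SECTION_LABELS: list[tuple[str, float]] = [
    ("Introduction", 0.20),
    ("Background", 0.10),
    ("Related Work", 0.10),
    ("Methods", 0.30),
    ("Results", 0.20),
    ("Discussion", 0.10),
]

_VENUES = ["J Synth Res", "Proc Synth Conf", "Synth Lett"]

# the head of the Zipf profile is occupied by function words, as in natural
# language; they break term chunks so filler n-grams stay low-C-value
_FILLER_STOPWORDS = (
    "the of and in to a is for with on that as are by this from at be or "
    "which an was were it not have has but can"
).split()


@dataclass(frozen=True)
class PlantedTerm:
    """A multi-word phrase injected into specific documents.

    ``doc_indices`` are positions in the generated document order; ``freq``
    is the number of occurrences planted per target document.
    """

    phrase: str
    doc_indices: tuple[int, ...]
    freq: int = 3


@dataclass
class GeneratorConfig:
    n_docs: int = 200
    vocab_size: int = 500
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    citation_density: float = 3.0
    section_labels: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_SECTION_LABELS)
    )
    year_range: tuple[int, int] = (2000, 2021)
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 2:
            raise ValueError("n_docs must be >= 2")
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (min, max) with min <= max")
        for term in self.planted_terms:
            if len(term.phrase.split()) < 2:
                raise ValueError(f"planted phrase must have >= 2 words: {term.phrase!r}")
            if term.freq < 0:
                raise ValueError("planted frequency must be >= 0")
            for idx in term.doc_indices:
                if not (0 <= idx < self.n_docs):
                    raise ValueError(
                        f"planted term {term.phrase!r} references doc index {idx} "
                        f"outside 0..{self.n_docs - 1}"
                    )


@dataclass
class GroundTruth:
    """What the generator planted: phrase locations and all citation mentions."""

    planted: list[tuple[str, str, int]] = field(default_factory=list)  # (phrase, doc_id, freq)
    mentions: list[CitationMention] = field(default_factory=list)

    def planted_in(self, doc_id: str) -> list[tuple[str, int]]:
        return [(p, f) for p, d, f in self.planted if d == doc_id]


def _zipf_probs(n: int, exponent: float = 1.1) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    probs = ranks ** -exponent
    return probs / probs.sum()


def doc_id_for(index: int) -> str:
    return f"D{index:04d}"


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth from the config alone."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_stop = min(len(_FILLER_STOPWORDS), config.vocab_size // 3)
    content = [f"w{i:03d}" for i in range(config.vocab_size - n_stop)]
    vocab = np.array(_FILLER_STOPWORDS[:n_stop] + content)
    probs = _zipf_probs(config.vocab_size)
    labels = [normalize_section(lbl) for lbl, _ in config.section_labels]
    label_w = np.array([w for _, w in config.section_labels], dtype=float)
    label_w = label_w / label_w.sum()

    def sentence(lo: int = 6, hi: int = 14) -> str:
        n = int(rng.integers(lo, hi + 1))
        return " ".join(rng.choice(vocab, size=n, p=probs)) + "."

    corpus = Corpus()
    truth = GroundTruth()
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=config.n_docs)

    # paragraphs stored as mutable sentence lists until planting is done
    para_sentences: list[list[list[str]]] = []
    abstracts: list[list[str]] = []
    for i in range(config.n_docs):
        title = " ".join(rng.choice(vocab, size=int(rng.integers(3, 7)), p=probs))
        abstracts.append([sentence(8, 15) for _ in range(2)])
        n_para = int(rng.integers(2, 7))
        paras = []
        for _ in range(n_para):
            n_sent = int(rng.integers(2, 6))
            paras.append([sentence() for _ in range(n_sent)])
        para_sentences.append(paras)
        corpus.add(
            Document(
                doc_id=doc_id_for(i),
                title=title,
                abstract="",
                year=int(years[i]),
                venue=_VENUES[i % len(_VENUES)],
                identifiers={"id": doc_id_for(i)},
            )
        )

    # plant phrases: occurrence 1 -> end of a body paragraph, occurrence 2 ->
    # abstract, later ones -> start or end of random paragraphs
    for term in config.planted_terms:
        phrase_sentence = term.phrase + "."
        for idx in term.doc_indices:
            paras = para_sentences[idx]
            for occ in range(term.freq):
                if occ == 1:
                    abstracts[idx].append(phrase_sentence)
                    continue
                p = int(rng.integers(0, len(paras)))
                if occ == 0 or rng.random() < 0.5:
                    paras[p].append(phrase_sentence)
                else:
                    paras[p].insert(0, phrase_sentence)
            if term.freq > 0:
                truth.planted.append((term.phrase, doc_id_for(idx), term.freq))

    # freeze text, assign section labels
    para_labels: list[list[str]] = []
    for i in range(config.n_docs):
        doc = corpus.documents[doc_id_for(i)]
        doc.abstract = " ".join(abstracts[i])
        chosen = [
            labels[int(j)]
            for j in rng.choice(len(labels), size=len(para_sentences[i]), p=label_w)
        ]
        para_labels.append(chosen)
        doc.paragraphs = [
            (chosen[p], " ".join(sents)) for p, sents in enumerate(para_sentences[i])
        ]

    # citations: targets restricted to same-year-or-older documents
    pair_counts: dict[tuple[str, str], int] = {}
    for i in range(config.n_docs):
        citing = doc_id_for(i)
        eligible = [j for j in range(config.n_docs) if j != i and years[j] <= years[i]]
        if not eligible:
            continue
        n_cites = int(rng.poisson(config.citation_density))
        for _ in range(n_cites):
            j = eligible[int(rng.integers(0, len(eligible)))]
            cited = doc_id_for(j)
            p = int(rng.integers(0, len(para_labels[i])))
            key = (citing, cited)
            idx = pair_counts.get(key, 0)
            pair_counts[key] = idx + 1
            mention = CitationMention(
                citing_id=citing,
                cited_id=cited,
                section_label=para_labels[i][p],
                mention_index=idx,
            )
            corpus.mentions.append(mention)
            truth.mentions.append(mention)
    return corpus, truth


def generate_qrels(
    corpus: Corpus, queries: list[str], config: GeneratorConfig | None = None
) -> Qrels:
    """Graded judgments from generated text, topics numbered from 1.

    Grade 2: the normalized query occurs verbatim (as a contiguous token
    sequence) in the document; grade 1: the document contains at least half
    of the query's distinct tokens; grade 0 otherwise (recorded explicitly).
    """
    qrels = Qrels()
    doc_tokens = {
        doc_id: tokenize(doc.text()) for doc_id, doc in corpus.documents.items()
    }
    for topic_no, query in enumerate(queries, 1):
        topic = str(topic_no)
        q = tuple(tokenize(query))
        for doc_id, toks in doc_tokens.items():
            grade = 0
            if q:
                if _contains_seq(toks, q):
                    grade = 2
                else:
                    present = sum(1 for t in set(q) if t in set(toks))
                    if present / len(set(q)) >= 0.5:
                        grade = 1
            qrels.add(topic, doc_id, grade)
    return qrels


def _contains_seq(haystack: list[str], needle: tuple[str, ...]) -> bool:
    m = len(needle)
    return any(tuple(haystack[i : i + m]) == needle for i in range(len(haystack) - m + 1))


def write_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write metadata.jsonl plus fulltext/*.json in the reader's own formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_metadata_jsonl(corpus, out_dir / "metadata.jsonl")
    write_fulltext_json(corpus, out_dir / "fulltext")
    return out_dir


def fixture_config(seed: int = 42) -> GeneratorConfig:
    """The small fixed corpus used in documentation examples and tests."""
    return GeneratorConfig(
        n_docs=20,
        vocab_size=120,
        planted_terms=[
            PlantedTerm("viral spike protein", (0, 3, 7), freq=4),
            PlantedTerm("community transmission chain", (2, 5), freq=3),
        ],
        citation_density=2.5,
        year_range=(2005, 2021),
        seed=seed,
    )
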