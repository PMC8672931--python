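"""Self-contained BM25 retrieval over four text-unit indexing schemes.

Schemes mirror the indexing experiments of term/citation exploratory search
over CORD-19-style corpora:

* ``full_text`` — one unit per document: title, abstract and all paragraphs.
* ``title_abstract`` — one unit per document: title and abstract only.
* ``paragraph`` — one unit per body paragraph, mapped back to the document.
* ``first_last_sentence`` — per paragraph, only its first and last sentence.

Sub-document schemes aggregate unit scores to documents by taking the
maximum (the standard passage-retrieval choice).  Ranking uses Okapi BM25
with k1=1.2, b=0.75 and the non-negative (Lucene-style) idf
``ln(1 + (N - df + 0.5)/(df + 0.5))``, so any unit containing at least one
query term scores strictly above the zero score of non-matching units.

Term-based reranking mixes min-max-normalized BM25 with a C-value-weighted
query/term-profile overlap score.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import Corpus
from .terms import TermScore, normalize_phrase, tokenize

SCHEMES = ("full_text", "title_abstract", "paragraph", "first_last_sentence")

K1 = 1.2
B = 0.75

# sentence boundary: ./?/! runs followed by whitespace; guarded abbreviations
# are masked first so they do not split
_ABBREVIATIONS = ("e.g.", "i.e.", "et al.", "etc.", "vs.", "fig.", "cf.", "approx.")
_SENT_RE = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[str]:
    masked = text
    for i, abbr in enumerate(_ABBREVIATIONS):
        masked = masked.replace(abbr, f"\x00{i}\x00")
    parts = [p.strip() for p in _SENT_RE.split(masked) if p.strip()]
    out = []
    for part in parts:
        for i, abbr in enumerate(_ABBREVIATIONS):
            part = part.replace(f"\x00{i}\x00", abbr)
        out.append(part)
    return out


@dataclass
class Index:
    """Inverted BM25 index over the units of one scheme."""

    scheme: str
    unit_doc: list[str]
    unit_len: list[int]
    avg_len: float
    n_units: int
    postings: dict[str, list[tuple[int, int]]]  # token -> [(unit, tf)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "unit_doc": self.unit_doc,
            "unit_len": self.unit_len,
            "postings": {t: p for t, p in sorted(self.postings.items())},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Index":
        payload = json.loads(Path(path).read_text())
        unit_len = payload["unit_len"]
        return cls(
            scheme=payload["scheme"],
            unit_doc=payload["unit_doc"],
            unit_len=unit_len,
            avg_len=sum(unit_len) / len(unit_len) if unit_len else 0.0,
            n_units=len(unit_len),
            postings={t: [tuple(x) for x in p] for t, p in payload["postings"].items()},
        )


@dataclass
class SearchResult:
    query: str
    ranking: list[tuple[str, float]]
    scheme: str
    reranked: bool = False

    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.ranking]


def _units_for(doc, scheme: str) -> list[str]:
    if scheme == "full_text":
        return [doc.text()]
    if scheme == "title_abstract":
        return [". ".join(p for p in (doc.title, doc.abstract) if p)]
    if scheme == "paragraph":
        return [text for _, text in doc.paragraphs]
    if scheme == "first_last_sentence":
        units = []
        for _, text in doc.paragraphs:
            sentences = split_sentences(text)
            if not sentences:
                continue
            if len(sentences) == 1:
                units.append(sentences[0])
            else:
                units.append(sentences[0] + " " + sentences[-1])
        return units
    raise ValueError(f"unknown indexing scheme: {scheme!r}")


def build_index(corpus: Corpus, scheme: str) -> Index:
    """Tokenized, lowercased inverted index over the scheme's text units."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown indexing scheme: {scheme!r}")
    if not corpus.documents:
        raise ValueError("cannot index an empty corpus")
    unit_doc: list[str] = []
    unit_len: list[int] = []
    postings: dict[str, list[tuple[int, int]]] = {}
    for doc_id in sorted(corpus.documents):
        doc = corpus.documents[doc_id]
        for unit_text in _units_for(doc, scheme):
            tokens = tokenize(unit_text)
            unit = len(unit_doc)
            unit_doc.append(doc_id)
            unit_len.append(len(tokens))
            for token, tf in Counter(tokens).items():
                postings.setdefault(token, []).append((unit, tf))
    avg = sum(unit_len) / len(unit_len) if unit_len else 0.0
    return Index(
        scheme=scheme,
        unit_doc=unit_doc,
        unit_len=unit_len,
        avg_len=avg,
        n_units=len(unit_doc),
        postings=postings,
    )


def _bm25_unit_scores(index: Index, query_tokens: Sequence[str]) -> dict[int, float]:
    scores: dict[int, float] = {}
    n = index.n_units
    for token in query_tokens:
        plist = index.postings.get(token)
        if not plist:
            continue
        df = len(plist)
        idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
        for unit, tf in plist:
            denom = tf + K1 * (1.0 - B + B * index.unit_len[unit] / index.avg_len)
            scores[unit] = scores.get(unit, 0.0) + idf * tf * (K1 + 1.0) / denom
    return scores


def search(index: Index, query: str, k: int = 50) -> SearchResult:
    """BM25 top-k documents; sub-document unit scores aggregate by maximum.

    A query with no indexed tokens yields an empty ranking.  Ties in score are
    broken by doc_id lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    unit_scores = _bm25_unit_scores(index, tokenize(query))
    doc_scores: dict[str, float] = {}
    for unit, score in unit_scores.items():
        doc_id = index.unit_doc[unit]
        if score > doc_scores.get(doc_id, 0.0):
            doc_scores[doc_id] = score
    ranking = sorted(doc_scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return SearchResult(query=query, ranking=ranking, scheme=index.scheme)


def term_rerank(
    result: SearchResult,
    query: str,
    profiles: Mapping[str, Sequence[TermScore]],
    lam: float = 0.5,
) -> SearchResult:
    """Rerank by mixing BM25 with C-value-weighted term overlap.

    The overlap score of a document is the sum of C-values of its profile
    terms whose surface occurs as a substring of the normalized query.  Final
    score: ``(1-lam) * minmax(bm25) + lam * minmax(overlap)``.  ``lam=0``
    returns the input ordering unchanged (flagged reranked).
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if lam == 0.0:
        return replace(result, reranked=True)
    missing = [d for d, _ in result.ranking if d not in profiles]
    if missing:
        raise ValueError(f"missing term profiles for: {missing}")
    norm_query = normalize_phrase(query)
    overlap = {
        doc_id: sum(s.cvalue for s in profiles[doc_id] if s.term in norm_query)
        for doc_id, _ in result.ranking
    }
    bm25 = dict(result.ranking)
    mm_b = _minmax(bm25)
    mm_o = _minmax(overlap)
    combined = {
        d: (1.0 - lam) * mm_b[d] + lam * mm_o[d] for d in bm25
    }
    ranking = sorted(combined.items(), key=lambda kv: (-kv[1], kv[0]))
    return SearchResult(query=result.query, ranking=ranking, scheme=result.scheme, reranked=True)


def _minmax(scores: Mapping[str, float]) -> dict[str, float]:
    if not scores:
        return {}
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        return {d: 0.0 for d in scores}
    return {d: (v - lo) / (hi - lo) for d, v in scores.items()}


def write_trec_run(
    results: Mapping[str, SearchResult], path: str | Path, tag: str = "litgraph"
) -> None:
    """Write rankings in TREC run format: ``topic Q0 docid rank score tag``."""
    with Path(path).open("w") as handle:
        for topic in sorted(results):
            for rank, (doc_id, score) in enumerate(results[topic].ranking, 1):
                handle.write(f"{topic} Q0 {doc_id} {rank} {score:.6f} {tag}\n")
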