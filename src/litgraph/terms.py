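"""C-value multi-word term extraction and ranking.

The C-value method scores candidate multi-word terms by combining their
length, frequency, and how often they occur *nested* inside longer candidate
terms.  For a candidate ``a`` of length ``|a|`` (in words) and frequency
``f(a)``:

* non-nested (no extracted longer candidate contains ``a``):
  ``C-value(a) = log2(|a|) * f(a)``
* nested in the candidate set ``T_a`` of longer extracted candidates
  containing ``a``:
  ``C-value(a) = log2(|a|) * (f(a) - (1/|T_a|) * sum_{b in T_a} f(b))``

Frequencies count every occurrence of the word sequence, both standalone and
inside longer candidates, within the scoring scope (a single document here;
collection-level importance is obtained by summing per-document scores, see
:func:`top_terms`).  Negative raw values are clamped to 0.

Candidate extraction uses a part-of-speech pattern ``(ADJ|NOUN)+ NOUN``: a
maximal run of adjective/noun tokens, trimmed so it ends in a noun, yields the
run itself plus all its contiguous subsequences within the configured length
band.  The default tagger is a lightweight heuristic (stopword/number
filtering); callers needing tagger-independent behaviour can pass pre-tagged
tokens to :func:`candidates_from_tagged`.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import Document

# Small closed-class stopword list; these tokens break candidate chunks.
STOPWORDS = frozenset(
    """a an the this that these those it its his her their our your my
    and or but nor so yet both either neither not no
    of in on at by for with from to into onto over under between among
    through during against about above below up down out off than as
    is are was were be been being am has have had having do does did done
    can could will would shall should may might must
    we they he she you i who whom whose which what where when why how
    there here very more most much many some any each such same other
    also then thus hence however therefore moreover further while if
    because although though since until unless whether per via using based
    et al eg ie""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")
_CHUNK_BREAK_RE = re.compile(r"[.,;:!?()\[\]{}\"]")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; punctuation stripped, hyphens kept internally."""
    return _TOKEN_RE.findall(text.lower())


def normalize_phrase(text: str) -> str:
    return " ".join(tokenize(text))


def heuristic_tag(token: str) -> str:
    """Tag a token NOUN if it can sit inside a term candidate, else O.

    Stopwords, bare numbers and single letters are excluded.  Without a
    trained tagger, content words are all treated as nouns; the trailing-noun
    trim of the ``(ADJ|NOUN)+ NOUN`` pattern is then a no-op.
    """
    if token in STOPWORDS or token.isdigit() or len(token) < 2:
        return "O"
    return "NOUN"


def tag_text(text: str) -> list[list[tuple[str, str]]]:
    """Split on chunk-breaking punctuation, tokenize and tag each fragment."""
    fragments = _CHUNK_BREAK_RE.split(text.lower())
    return [[(tok, heuristic_tag(tok)) for tok in tokenize(frag)] for frag in fragments]


@dataclass(frozen=True)
class TermCandidate:
    """A candidate term: normalized surface, word count, and frequency."""

    surface: str
    length: int
    freq: int


@dataclass(frozen=True)
class TermScore:
    term: str
    doc_id: str | None
    cvalue: float


def _chunks_from_tagged(tagged: Sequence[tuple[str, str]]) -> list[tuple[str, ...]]:
    """Maximal (ADJ|NOUN)+ NOUN runs in one tagged fragment."""
    chunks: list[tuple[str, ...]] = []
    run: list[tuple[str, str]] = []
    for tok, tag in list(tagged) + [("", "O")]:
        if tag in ("ADJ", "NOUN", "PROPN"):
            run.append((tok, tag))
        else:
            if run:
                # trim trailing adjectives so the pattern ends in a noun
                while run and run[-1][1] == "ADJ":
                    run.pop()
                if run:
                    chunks.append(tuple(t for t, _ in run))
                run = []
    return chunks


def candidates_from_tagged(
    fragments: Iterable[Sequence[tuple[str, str]]],
    min_len: int = 2,
    max_len: int = 6,
) -> list[TermCandidate]:
    """Candidates from pre-tagged fragments (tagger-independent entry point).

    Every maximal pattern match contributes all its contiguous subsequences of
    length ``min_len..max_len``; frequencies count occurrences standalone and
    nested inside longer matches.
    """
    if not (2 <= min_len <= max_len <= 8):
        raise ValueError("require 2 <= min_len <= max_len <= 8")
    counts: Counter[tuple[str, ...]] = Counter()
    for fragment in fragments:
        for chunk in _chunks_from_tagged(fragment):
            n = len(chunk)
            for length in range(min_len, min(max_len, n) + 1):
                for start in range(n - length + 1):
                    counts[chunk[start : start + length]] += 1
    return [
        TermCandidate(surface=" ".join(words), length=len(words), freq=freq)
        for words, freq in sorted(counts.items())
    ]


def extract_candidates(text: str, min_len: int = 2, max_len: int = 6) -> list[TermCandidate]:
    """Extract multi-word term candidates from raw text (heuristic tagging)."""
    if not text or not text.strip():
        return []
    return candidates_from_tagged(tag_text(text), min_len=min_len, max_len=max_len)


def compute_cvalue(
    candidates: Sequence[TermCandidate], doc_id: str | None = None
) -> list[TermScore]:
    """Score candidates with the C-value formula.

    Returns one :class:`TermScore` per candidate, sorted by C-value descending
    with alphabetical tie-break; negative raw values are clamped to 0.
    """
    toks = {c.surface: tuple(c.surface.split()) for c in candidates}
    scores: list[TermScore] = []
    for cand in candidates:
        a = toks[cand.surface]
        nest_freqs = [
            other.freq
            for other in candidates
            if other.length > cand.length and _contains(toks[other.surface], a)
        ]
        raw = cand.freq
        if nest_freqs:
            raw = cand.freq - sum(nest_freqs) / len(nest_freqs)
        cvalue = max(0.0, math.log2(cand.length) * raw)
        scores.append(TermScore(term=cand.surface, doc_id=doc_id, cvalue=cvalue))
    scores.sort(key=lambda s: (-s.cvalue, s.term))
    return scores


def _contains(longer: tuple[str, ...], shorter: tuple[str, ...]) -> bool:
    n, m = len(longer), len(shorter)
    return any(longer[i : i + m] == shorter for i in range(n - m + 1))


def doc_term_profile(
    doc: Document, top_k: int = 50, min_len: int = 2, max_len: int = 6
) -> list[TermScore]:
    """Top-k C-value term profile of one document (title+abstract+body)."""
    candidates = extract_candidates(doc.text(), min_len=min_len, max_len=max_len)
    return compute_cvalue(candidates, doc_id=doc.doc_id)[:top_k]


def top_terms(
    docs: Iterable[Document], top_k: int = 50, min_len: int = 2, max_len: int = 6
) -> list[tuple[str, float]]:
    """Aggregate term importance over a document set.

    Per-document C-values are summed across documents; the top-k (term,
    aggregate) pairs feed the bubble-cloud view and the Terms tab listing.
    """
    docs = list(docs)
    if not docs:
        raise ValueError("document set must be non-empty")
    totals: dict[str, float] = {}
    for doc in docs:
        for score in doc_term_profile(doc, top_k=10**9, min_len=min_len, max_len=max_len):
            totals[score.term] = totals.get(score.term, 0.0) + score.cvalue
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def profile_to_records(profile: Sequence[TermScore]) -> list[dict]:
    """Tabular form (term, doc_id, cvalue) for TSV/JSON serialization."""
    return [{"term": s.term, "doc_id": s.doc_id, "cvalue": s.cvalue} for s in profile]


def bubble_cloud_feed(pairs: Sequence[tuple[str, float]]) -> list[dict]:
    """(term, weight) JSON feed consumed by the bubble-cloud front end."""
    return [{"term": t, "weight": w} for t, w in pairs]
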