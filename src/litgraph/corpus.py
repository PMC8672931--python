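"""Core document model and readers/writers for CORD-19-style corpora.

A :class:`Corpus` holds :class:`Document` records (metadata plus ordered,
section-labelled paragraphs) and a flat list of :class:`CitationMention`
records extracted from in-text citation spans.  Two metadata dialects are
supported: the CORD-19 ``metadata.csv`` column layout and a minimal
one-JSON-object-per-line layout.  Full text follows the CORD-19 JSON shape
(``body_text`` entries with ``cite_spans``, ``bib_entries`` keyed by ref id).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Marker for an in-text citation whose bibliography entry could not be
#: resolved to a document in the corpus.
UNRESOLVED = None

#: Section-label aliases mapping a normalized raw label to its section class.
#: Labels not matched here fall through to their own normalized form, which
#: section weighting treats as the "other" class.
DEFAULT_SECTION_ALIASES: dict[str, str] = {
    "introduction": "introduction",
    "intro": "introduction",
    "background": "background",
    "related work": "related_work",
    "related works": "related_work",
    "literature review": "related_work",
    "prior work": "related_work",
}

_PUNCT_RE = re.compile(r"[^\w\s]")


def normalize_section(label: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a raw section heading to a section class name.

    Lowercases, strips punctuation and digits-only decorations, collapses
    whitespace, then maps through the alias table.  Unmatched labels are
    returned in normalized form (treated downstream as "other").
    """
    if aliases is None:
        aliases = DEFAULT_SECTION_ALIASES
    norm = _PUNCT_RE.sub(" ", label.lower())
    norm = re.sub(r"\b\d+\b", " ", norm)
    norm = " ".join(norm.split())
    return aliases.get(norm, norm if norm else "other")


@dataclass
class Document:
    """One publication: metadata plus ordered (section, text) paragraphs."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    paragraphs: list[tuple[str, str]] = field(default_factory=list)
    year: int | None = None
    venue: str | None = None
    #: identifier fields (doi, pmcid, internal id ...) used for citation
    #: resolution; matching is case-insensitive on values
    identifiers: dict[str, str] = field(default_factory=dict)

    def text(self) -> str:
        """Title, abstract and body joined with sentence-breaking separators."""
        parts = [self.title, self.abstract] + [t for _, t in self.paragraphs]
        return ". ".join(p for p in parts if p)


@dataclass
class CitationMention:
    """A single in-text citation occurrence.

    ``cited_id`` is ``None`` (:data:`UNRESOLVED`) when the bibliography entry
    did not match any corpus document; such mentions are retained but excluded
    from edge computation.  ``mention_index`` numbers the mentions of one
    (citing, cited) pair from 0, so the pair's mention count is the citation
    repetition count N.
    """

    citing_id: str
    cited_id: str | None
    section_label: str
    mention_index: int = 0

    @property
    def resolved(self) -> bool:
        return self.cited_id is not None


@dataclass
class Corpus:
    documents: dict[str, Document] = field(default_factory=dict)
    mentions: list[CitationMention] = field(default_factory=list)
    #: metadata rows dropped for missing doc_id
    skipped_rows: int = 0

    def __len__(self) -> int:
        return len(self.documents)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self.documents

    def add(self, doc: Document) -> None:
        if not doc.doc_id:
            raise ValueError("doc_id must be non-empty")
        if doc.doc_id in self.documents:
            raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
        self.documents[doc.doc_id] = doc

    def resolved_mentions(self) -> list[CitationMention]:
        return [m for m in self.mentions if m.resolved]

    def identifier_index(self) -> dict[str, str]:
        """Map every known identifier value (lowercased) to its doc_id."""
        index: dict[str, str] = {}
        for doc in self.documents.values():
            index[doc.doc_id.lower()] = doc.doc_id
            for value in doc.identifiers.values():
                if value:
                    index[str(value).lower()] = doc.doc_id
        return index


def _truncate_year(value: object) -> int | None:
    """Extract a 4-digit year from a date-ish value, else None."""
    if value is None:
        return None
    if isinstance(value, (int, float)) and not pd.isna(value):
        year = int(value)
        return year if 1000 <= year <= 9999 else None
    text = str(value).strip()
    m = re.match(r"(\d{4})", text)
    return int(m.group(1)) if m else None


def read_metadata(path: str | Path, dialect: str = "cord19_csv") -> Corpus:
    """Read a metadata table into a Corpus (no paragraphs, no mentions).

    Dialects: ``cord19_csv`` (columns cord_uid, title, abstract, publish_time,
    journal, doi; extras ignored) and ``simple_jsonl`` (per-line objects with
    id, title, abstract, year, venue).  Rows with a missing id are skipped and
    counted in ``Corpus.skipped_rows``; duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    corpus = Corpus()
    if dialect == "cord19_csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row in frame.to_dict("records"):
            doc_id = (row.get("cord_uid") or "").strip()
            if not doc_id:
                corpus.skipped_rows += 1
                continue
            identifiers = {"cord_uid": doc_id}
            if row.get("doi"):
                identifiers["doi"] = row["doi"].strip()
            corpus.add(
                Document(
                    doc_id=doc_id,
                    title=row.get("title", ""),
                    abstract=row.get("abstract", ""),
                    year=_truncate_year(row.get("publish_time")),
                    venue=row.get("journal") or None,
                    identifiers=identifiers,
                )
            )
    elif dialect == "simple_jsonl":
        with path.open() as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"parse error in {path} line {lineno}: {exc}") from exc
                doc_id = str(row.get("id") or "").strip()
                if not doc_id:
                    corpus.skipped_rows += 1
                    continue
                corpus.add(
                    Document(
                        doc_id=doc_id,
                        title=row.get("title", ""),
                        abstract=row.get("abstract", ""),
                        year=_truncate_year(row.get("year")),
                        venue=row.get("venue"),
                        identifiers={"id": doc_id},
                    )
                )
    else:
        raise ValueError(f"unknown metadata dialect: {dialect!r}")
    return corpus


def read_fulltext(
    path: str | Path,
    corpus: Corpus,
    aliases: Mapping[str, str] | None = None,
) -> Corpus:
    """Attach full text and citation mentions from a CORD-19-shaped JSON file.

    The file must carry ``paper_id`` (a doc_id already present in the corpus),
    ``body_text`` — a list of ``{section, text, cite_spans: [{ref_id}]}`` — and
    ``bib_entries`` mapping ref ids to identifier records (``doi`` and/or
    ``other_ids``).  Each cite span whose bibliography entry matches a corpus
    document by any identifier (case-insensitive) yields one resolved
    :class:`CitationMention` labelled with its paragraph's section class;
    non-matching spans are retained unresolved.  Mutates and returns *corpus*.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc

    doc_id = str(payload.get("paper_id") or "")
    if doc_id not in corpus:
        raise ValueError(f"doc_id {doc_id!r} from {path} not present in corpus metadata")
    doc = corpus.documents[doc_id]

    id_index = corpus.identifier_index()
    bib = payload.get("bib_entries", {}) or {}

    def resolve(ref_id: str) -> str | None:
        entry = bib.get(ref_id)
        if not isinstance(entry, dict):
            return None
        values: list[str] = []
        if entry.get("doi"):
            values.append(str(entry["doi"]))
        other = entry.get("other_ids") or {}
        if isinstance(other, dict):
            for val in other.values():
                if isinstance(val, (list, tuple)):
                    values.extend(str(v) for v in val)
                elif val:
                    values.append(str(val))
        for value in values:
            hit = id_index.get(value.lower())
            if hit is not None and hit != doc_id:
                return hit
        return None

    pair_counts: dict[tuple[str, str | None], int] = {}
    for mention in corpus.mentions:
        key = (mention.citing_id, mention.cited_id)
        pair_counts[key] = max(pair_counts.get(key, 0), mention.mention_index + 1)

    doc.paragraphs = []
    body = payload.get("body_text")
    if not isinstance(body, list):
        raise ValueError(f"parse error in {path}: body_text must be a list")
    for entry in body:
        section = normalize_section(str(entry.get("section", "")), aliases)
        text = str(entry.get("text", ""))
        doc.paragraphs.append((section, text))
        for span in entry.get("cite_spans", []) or []:
            cited = resolve(str(span.get("ref_id", "")))
            key = (doc_id, cited)
            idx = pair_counts.get(key, 0)
            pair_counts[key] = idx + 1
            corpus.mentions.append(
                CitationMention(
                    citing_id=doc_id,
                    cited_id=cited,
                    section_label=section,
                    mention_index=idx,
                )
            )
    return corpus


def read_corpus(
    metadata_path: str | Path,
    fulltext_dir: str | Path | None = None,
    dialect: str = "simple_jsonl",
) -> Corpus:
    """Convenience loader: metadata plus every ``*.json`` under *fulltext_dir*."""
    corpus = read_metadata(metadata_path, dialect=dialect)
    if fulltext_dir is not None:
        for path in sorted(Path(fulltext_dir).glob("*.json")):
            read_fulltext(path, corpus)
    return corpus


# ---------------------------------------------------------------------------
# Writers (used by the synthetic generator so generated corpora exercise the
# same readers as real data).
# ---------------------------------------------------------------------------

def write_metadata_jsonl(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        for doc_id in sorted(corpus.documents):
            doc = corpus.documents[doc_id]
            handle.write(
                json.dumps(
                    {
                        "id": doc.doc_id,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "year": doc.year,
                        "venue": doc.venue,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def write_fulltext_json(corpus: Corpus, out_dir: str | Path) -> list[Path]:
    """Write one CORD-19-shaped full-text JSON file per document.

    Citation mentions are embedded as cite spans on their source paragraphs;
    bibliography entries expose the cited document's identifiers so the reader
    can resolve them again.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_doc: dict[str, list[CitationMention]] = {}
    for mention in corpus.mentions:
        by_doc.setdefault(mention.citing_id, []).append(mention)

    paths = []
    for doc_id in sorted(corpus.documents):
        doc = corpus.documents[doc_id]
        mentions = by_doc.get(doc_id, [])
        bib: dict[str, dict] = {}
        ref_for_cited: dict[str | None, str] = {}
        for mention in mentions:
            if mention.cited_id not in ref_for_cited:
                ref_id = f"BIBREF{len(ref_for_cited)}"
                ref_for_cited[mention.cited_id] = ref_id
                if mention.cited_id is None:
                    bib[ref_id] = {"doi": "", "other_ids": {}}
                else:
                    cited = corpus.documents[mention.cited_id]
                    bib[ref_id] = {
                        "doi": cited.identifiers.get("doi", ""),
                        "other_ids": {"id": [mention.cited_id]},
                    }
        # mentions are attached to the first paragraph carrying their section
        # label; the generator keeps labels and mentions consistent
        body = []
        for para_idx, (section, text) in enumerate(doc.paragraphs):
            spans = [
                {"ref_id": ref_for_cited[m.cited_id]}
                for m in mentions
                if m.section_label == section
                and _first_paragraph_with(doc, section) == para_idx
            ]
            body.append({"section": section, "text": text, "cite_spans": spans})
        payload = {"paper_id": doc_id, "body_text": body, "bib_entries": bib}
        path = out_dir / f"{doc_id}.json"
        path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
        paths.append(path)
    return paths


def _first_paragraph_with(doc: Document, section: str) -> int | None:
    for idx, (label, _) in enumerate(doc.paragraphs):
        if label == section:
            return idx
    return None


def subset(corpus: Corpus, doc_ids: Iterable[str]) -> Corpus:
    """A new Corpus restricted to *doc_ids* (mentions kept if the citing
    document survives; cited ends outside the subset become part of the wider
    corpus context and should be looked up there)."""
    keep = set(doc_ids)
    sub = Corpus(skipped_rows=corpus.skipped_rows)
    for doc_id in keep:
        if doc_id in corpus.documents:
            sub.add(corpus.documents[doc_id])
    sub.mentions = [m for m in corpus.mentions if m.citing_id in keep]
    return sub
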