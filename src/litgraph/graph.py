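"""Weighted, directed, typed document graphs over a search-result set.

Three edge types connect retrieved documents:

* **term edges** — a term ``t`` in the top-T C-value profiles of both
  documents ``a`` and ``b`` yields an edge of weight
  ``w = (Cvalue_t(a) + Cvalue_t(b)) / 2``, labelled ``t``; multiple shared
  terms yield parallel edges.
* **direct citation edges** — ``a`` citing ``b`` with ``N`` in-text mentions
  yields ``w = N * max_i(sw_i) / max(1, year_a - year_b)`` where ``sw_i`` is
  the section weight of mention ``i`` (introduction / related-work /
  background citations count less) and the denominator is the publication
  year gap floored at 1 (also used when a year is missing or negative).
* **indirect (co-citation) edges** — documents ``a`` and ``b`` citing a
  common set ``C`` of documents yield
  ``w = sum_{c in C} (wcd_ac + wcd_bc) / (2 * |C|)``, the mean pairwise
  direct-citation strength toward the shared references (which need not be
  in the graph themselves).

Edges are directed from the newer to the older publication (citation edges
follow citation order); on equal or missing years, the lexicographically
smaller doc_id is the source.  Graphs can be threshold-filtered, expanded
one node at a time, and exported as d3-compatible node-link JSON or GraphML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .corpus import Corpus
from .retrieval import SearchResult
from .terms import TermScore, doc_term_profile

EDGE_KINDS = ("term", "direct_citation", "indirect_citation")


@dataclass
class SectionWeights:
    """Per-section citation significance weights ``sw`` in (0, 1].

    Citations in framing sections (introduction, related work, background)
    weigh less than citations elsewhere; unknown section classes fall back to
    the mandatory "other" class.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {
            "introduction": 0.5,
            "related_work": 0.5,
            "background": 0.5,
            "other": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if "other" not in self.weights:
            raise ValueError('SectionWeights must define an "other" class')
        for cls, w in self.weights.items():
            if not (0.0 < w <= 1.0):
                raise ValueError(f"section weight for {cls!r} must be in (0, 1]")

    def get(self, section_class: str) -> float:
        return self.weights.get(section_class, self.weights["other"])


@dataclass(frozen=True)
class Edge:
    source: str  # newer / citing end
    target: str  # older / cited end
    kind: str
    weight: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-loop edge")
        if self.weight <= 0:
            raise ValueError("edge weight must be positive")
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind: {self.kind!r}")
        if self.kind == "term" and not self.label:
            raise ValueError("term edges must carry the cooccurring term label")


@dataclass
class DocumentGraph:
    """Node-link model: nodes carry query relevance and an origin flag."""

    nodes: list[tuple[str, float, str]] = field(default_factory=list)  # (id, relevance, origin)
    edges: list[Edge] = field(default_factory=list)

    def node_ids(self) -> set[str]:
        return {n for n, _, _ in self.nodes}


def _direction(a: str, b: str, corpus: Corpus) -> tuple[str, str]:
    """Order a pair newest -> oldest; ties/missing years by doc_id."""
    ya = corpus.documents[a].year if a in corpus else None
    yb = corpus.documents[b].year if b in corpus else None
    if ya is not None and yb is not None and ya != yb:
        return (a, b) if ya > yb else (b, a)
    return (a, b) if a < b else (b, a)


def build_term_edges(
    result: SearchResult,
    profiles: Mapping[str, Sequence[TermScore]],
    corpus: Corpus,
    top_t: int = 10,
) -> list[Edge]:
    """Term-cooccurrence edges between all result pairs sharing profile terms.

    Only the top-T profile entries per document participate (bounds the edge
    count); every shared term yields its own parallel edge weighted by the
    average of the two per-document C-values.
    """
    doc_ids = result.doc_ids()
    missing = [d for d in doc_ids if d not in profiles]
    if missing:
        raise ValueError(f"missing term profiles for: {missing}")
    top = {
        d: {s.term: s.cvalue for s in list(profiles[d])[:top_t]} for d in doc_ids
    }
    edges: list[Edge] = []
    for i, a in enumerate(doc_ids):
        for b in doc_ids[i + 1 :]:
            shared = sorted(set(top[a]) & set(top[b]))
            src, dst = _direction(a, b, corpus)
            for term in shared:
                weight = (top[a][term] + top[b][term]) / 2.0
                if weight > 0:
                    edges.append(Edge(src, dst, "term", weight, label=term))
    return edges


def _pair_mentions(corpus: Corpus) -> dict[tuple[str, str], list[str]]:
    """(citing, cited) -> section labels of the pair's resolved mentions."""
    pairs: dict[tuple[str, str], list[str]] = {}
    for m in corpus.mentions:
        if m.resolved:
            pairs.setdefault((m.citing_id, m.cited_id), []).append(m.section_label)
    return pairs


def direct_citation_weight(
    corpus: Corpus, citing: str, cited: str, sw: SectionWeights,
    _pairs: Mapping[tuple[str, str], list[str]] | None = None,
) -> float | None:
    """``N * max_i(sw_i) / max(1, year_a - year_b)`` for one citing pair.

    Returns None when the pair has no resolved mentions.
    """
    pairs = _pairs if _pairs is not None else _pair_mentions(corpus)
    sections = pairs.get((citing, cited))
    if not sections:
        return None
    n = len(sections)
    max_sw = max(sw.get(s) for s in sections)
    ya = corpus.documents[citing].year
    yb = corpus.documents[cited].year
    gap = 1 if ya is None or yb is None else max(1, ya - yb)
    return n * max_sw / gap


def build_direct_citation_edges(
    doc_ids: Sequence[str], corpus: Corpus, sw: SectionWeights | None = None
) -> list[Edge]:
    """Direct citation edges among *doc_ids*, directed citing -> cited."""
    sw = sw or SectionWeights()
    node_set = set(doc_ids)
    pairs = _pair_mentions(corpus)
    edges = []
    for (citing, cited), sections in sorted(pairs.items()):
        if citing in node_set and cited in node_set:
            w = direct_citation_weight(corpus, citing, cited, sw, _pairs=pairs)
            if w:
                edges.append(Edge(citing, cited, "direct_citation", w))
    return edges


def build_indirect_citation_edges(
    doc_ids: Sequence[str], corpus: Corpus, sw: SectionWeights | None = None
) -> list[Edge]:
    """Co-citation edges: one per node pair with a non-empty common cited set.

    The shared references themselves need not belong to the node set.
    """
    sw = sw or SectionWeights()
    pairs = _pair_mentions(corpus)
    cited_by: dict[str, set[str]] = {d: set() for d in doc_ids}
    for citing, cited in pairs:
        if citing in cited_by:
            cited_by[citing].add(cited)
    edges = []
    ids = list(doc_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            common = cited_by[a] & cited_by[b]
            if not common:
                continue
            total = 0.0
            for c in common:
                wa = direct_citation_weight(corpus, a, c, sw, _pairs=pairs)
                wb = direct_citation_weight(corpus, b, c, sw, _pairs=pairs)
                total += (wa or 0.0) + (wb or 0.0)
            weight = total / (2.0 * len(common))
            if weight > 0:
                src, dst = _direction(a, b, corpus)
                edges.append(Edge(src, dst, "indirect_citation", weight))
    return edges


def assemble_graph(result: SearchResult, *edge_sets: Sequence[Edge]) -> DocumentGraph:
    """Combine retrieval relevance and typed edge sets into one multigraph."""
    nodes = [(doc_id, score, "initial") for doc_id, score in result.ranking]
    node_ids = {n for n, _, _ in nodes}
    edges: list[Edge] = []
    for edge_set in edge_sets:
        for edge in edge_set:
            if edge.source not in node_ids or edge.target not in node_ids:
                raise ValueError(
                    f"edge endpoint not in node set: {edge.source}->{edge.target}"
                )
            edges.append(edge)
    return DocumentGraph(nodes=nodes, edges=edges)


def build_graph(
    result: SearchResult,
    corpus: Corpus,
    profiles: Mapping[str, Sequence[TermScore]] | None = None,
    sw: SectionWeights | None = None,
    top_t: int = 10,
) -> DocumentGraph:
    """Convenience: all three edge types for a search result, assembled."""
    if profiles is None:
        profiles = {
            d: doc_term_profile(corpus.documents[d]) for d in result.doc_ids()
        }
    sw = sw or SectionWeights()
    doc_ids = result.doc_ids()
    return assemble_graph(
        result,
        build_term_edges(result, profiles, corpus, top_t=top_t),
        build_direct_citation_edges(doc_ids, corpus, sw),
        build_indirect_citation_edges(doc_ids, corpus, sw),
    )


def filter_by_threshold(graph: DocumentGraph, tau: float) -> DocumentGraph:
    """Keep edges of weight >= tau; nodes are retained even if isolated."""
    if tau < 0:
        raise ValueError("threshold must be non-negative")
    return DocumentGraph(
        nodes=list(graph.nodes),
        edges=[e for e in graph.edges if e.weight >= tau],
    )


def expand_node(
    graph: DocumentGraph,
    doc_id: str,
    corpus: Corpus,
    profiles: Mapping[str, Sequence[TermScore]] | None = None,
    sw: SectionWeights | None = None,
    m: int = 10,
    top_t: int = 10,
) -> DocumentGraph:
    """Add the m strongest out-of-graph neighbours of one node.

    All three edge types between *doc_id* and corpus documents not currently
    in the graph are computed; candidates are ranked by their strongest edge,
    the top m join with origin="expanded" and relevance 0 together with their
    connecting edges.  A no-op when no new neighbours exist or m=0.
    """
    node_ids = graph.node_ids()
    if doc_id not in node_ids:
        raise ValueError(f"unknown node: {doc_id!r}")
    if m == 0:
        return DocumentGraph(nodes=list(graph.nodes), edges=list(graph.edges))
    sw = sw or SectionWeights()
    outside = sorted(set(corpus.documents) - node_ids)
    if profiles is None:
        profiles = {
            d: doc_term_profile(corpus.documents[d]) for d in [doc_id] + outside
        }
    candidate_edges: dict[str, list[Edge]] = {}
    for other in outside:
        pair_result = SearchResult(query="", ranking=[(doc_id, 0.0), (other, 0.0)], scheme="")
        edges = (
            build_term_edges(pair_result, profiles, corpus, top_t=top_t)
            + build_direct_citation_edges([doc_id, other], corpus, sw)
            + build_indirect_citation_edges([doc_id, other], corpus, sw)
        )
        if edges:
            candidate_edges[other] = edges
    ranked = sorted(
        candidate_edges.items(), key=lambda kv: (-max(e.weight for e in kv[1]), kv[0])
    )[:m]
    new_nodes = list(graph.nodes) + [(d, 0.0, "expanded") for d, _ in ranked]
    new_edges = list(graph.edges)
    for _, edges in ranked:
        new_edges.extend(edges)
    return DocumentGraph(nodes=new_nodes, edges=new_edges)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def to_networkx(graph: DocumentGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for doc_id, relevance, origin in graph.nodes:
        g.add_node(doc_id, relevance=float(relevance), origin=origin)
    for edge in graph.edges:
        g.add_edge(
            edge.source, edge.target,
            kind=edge.kind, weight=float(edge.weight), label=edge.label,
        )
    return g


def from_networkx(g: nx.MultiDiGraph) -> DocumentGraph:
    nodes = [
        (str(n), float(d.get("relevance", 0.0)), str(d.get("origin", "initial")))
        for n, d in g.nodes(data=True)
    ]
    edges = [
        Edge(str(u), str(v), d["kind"], float(d["weight"]), d.get("label", ""))
        for u, v, d in g.edges(data=True)
    ]
    return DocumentGraph(nodes=nodes, edges=edges)


def export_graph(graph: DocumentGraph, path: str | Path, fmt: str = "nodelink_json") -> Path:
    """Serialize as d3-compatible node-link JSON or GraphML."""
    path = Path(path)
    if fmt == "nodelink_json":
        payload = {
            "nodes": [
                {"id": n, "relevance": r, "origin": o} for n, r, o in graph.nodes
            ],
            "links": [
                {
                    "source": e.source,
                    "target": e.target,
                    "kind": e.kind,
                    "weight": e.weight,
                    "label": e.label,
                }
                for e in graph.edges
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(graph), path)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return path


def import_graph(path: str | Path, fmt: str = "nodelink_json") -> DocumentGraph:
    path = Path(path)
    if fmt == "nodelink_json":
        payload = json.loads(path.read_text())
        nodes = [
            (d["id"], float(d["relevance"]), d["origin"]) for d in payload["nodes"]
        ]
        edges = [
            Edge(d["source"], d["target"], d["kind"], float(d["weight"]), d.get("label", ""))
            for d in payload["links"]
        ]
        return DocumentGraph(nodes=nodes, edges=edges)
    if fmt == "graphml":
        return from_networkx(nx.read_graphml(path, force_multigraph=True))
    raise ValueError(f"unknown export format: {fmt!r}")
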