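import random

import pytest

from litgraph import graph as gb
from litgraph.corpus import CitationMention, Corpus, Document
from litgraph.retrieval import SearchResult
from litgraph.terms import TermScore

from .conftest import tiny_corpus
from .oracles import oracle_direct_weights, oracle_indirect_weights, oracle_term_edges

SECTIONS = ["introduction", "related_work", "background", "methods", "results"]


def mention(a, b, section, idx=0):
    return CitationMention(citing_id=a, cited_id=b, section_label=section, mention_index=idx)


def profile(doc_id, pairs):
    return [TermScore(term=t, doc_id=doc_id, cvalue=c) for t, c in pairs]


def random_instance(rng, n_docs=6, missing_years=True):
    """A small random corpus: years, mention table, term profiles."""
    ids = [f"P{i}" for i in range(n_docs)]
    corpus = Corpus()
    years = {}
    for d in ids:
        year = None if missing_years and rng.random() < 0.15 else rng.randint(2015, 2021)
        years[d] = year
        corpus.add(Document(doc_id=d, year=year))
    table = []
    for _ in range(rng.randint(0, 12)):
        a, b = rng.sample(ids, 2)
        table.append((a, b, rng.choice(SECTIONS)))
    pair_idx = {}
    for a, b, s in table:
        idx = pair_idx.get((a, b), 0)
        pair_idx[(a, b)] = idx + 1
        corpus.mentions.append(mention(a, b, s, idx))
    pool = ["spike protein", "viral load", "contact tracing", "case count",
            "host cell", "immune response"]
    profiles = {
        d: profile(d, [(t, round(rng.uniform(0.5, 8.0), 3))
                       for t in rng.sample(pool, rng.randint(1, 4))])
        for d in ids
    }
    return corpus, years, profiles


class TestTermEdges:
    def test_shared_term_weight_is_average_cvalue(self):
        corpus = tiny_corpus([("A", 2021), ("B", 2019)])
        result = SearchResult("q", [("A", 1.0), ("B", 0.5)], "full_text")
        profiles = {
            "A": profile("A", [("spike protein", 4.0)]),
            "B": profile("B", [("spike protein", 2.0)]),
        }
        (edge,) = gb.build_term_edges(result, profiles, corpus)
        assert edge.weight == 3.0
        assert edge.kind == "term"
        assert edge.label == "spike protein"
        assert (edge.source, edge.target) == ("A", "B")  # newer -> older

    def test_no_shared_terms_no_edge(self):
        corpus = tiny_corpus([("A", 2021), ("B", 2019)])
        result = SearchResult("q", [("A", 1.0), ("B", 0.5)], "full_text")
        profiles = {
            "A": profile("A", [("spike protein", 4.0)]),
            "B": profile("B", [("viral load", 2.0)]),
        }
        assert gb.build_term_edges(result, profiles, corpus) == []

    def test_parallel_edges_for_multiple_shared_terms(self):
        corpus = tiny_corpus([("A", 2021), ("B", 2019), ("C", 2018)])
        result = SearchResult("q", [("A", 1.0), ("B", 0.7), ("C", 0.3)], "full_text")
        profiles = {
            "A": profile("A", [("spike protein", 4.0), ("viral load", 2.0)]),
            "B": profile("B", [("spike protein", 2.0), ("viral load", 6.0)]),
            "C": profile("C", [("contact tracing", 1.0)]),
        }
        edges = gb.build_term_edges(result, profiles, corpus)
        assert len(edges) == 2
        assert {e.label for e in edges} == {"spike protein", "viral load"}

    def test_only_top_t_profile_terms_participate(self):
        corpus = tiny_corpus([("A", 2021), ("B", 2019)])
        result = SearchResult("q", [("A", 1.0), ("B", 0.5)], "full_text")
        profiles = {
            "A": profile("A", [("alpha beta", 9.0), ("spike protein", 1.0)]),
            "B": profile("B", [("spike protein", 1.0)]),
        }
        assert gb.build_term_edges(result, profiles, corpus, top_t=1) == []

    def test_missing_profile_names_the_document(self):
        corpus = tiny_corpus([("A", 2021), ("B", 2019)])
        result = SearchResult("q", [("A", 1.0), ("B", 0.5)], "full_text")
        with pytest.raises(ValueError, match="B"):
            gb.build_term_edges(result, {"A": []}, corpus)


class TestDirectCitationEdges:
    def test_worked_example(self):
        # 3 mentions in sections weighted {0.5, 1.0, 0.5}, years 2021 -> 2019
        corpus = tiny_corpus(
            [("A", 2021), ("B", 2019)],
            [mention("A", "B", "introduction", 0),
             mention("A", "B", "methods", 1),
             mention("A", "B", "related_work", 2)],
        )
        (edge,) = gb.build_direct_citation_edges(["A", "B"], corpus)
        assert edge.weight == pytest.approx(3 * 1.0 / 2)
        assert (edge.source, edge.target) == ("A", "B")

    def test_same_year_denominator_floors_at_one(self):
        corpus = tiny_corpus([("A", 2020), ("B", 2020)],
                             [mention("A", "B", "methods")])
        (edge,) = gb.build_direct_citation_edges(["A", "B"], corpus)
        assert edge.weight == pytest.approx(1.0)

    def test_missing_year_uses_denominator_one(self):
        corpus = tiny_corpus([("A", None), ("B", 2010)],
                             [mention("A", "B", "introduction")])
        (edge,) = gb.build_direct_citation_edges(["A", "B"], corpus)
        assert edge.weight == pytest.approx(0.5)

    def test_pairs_outside_node_set_excluded(self):
        corpus = tiny_corpus([("A", 2021), ("B", 2019), ("C", 2018)],
                             [mention("A", "C", "methods")])
        assert gb.build_direct_citation_edges(["A", "B"], corpus) == []

    def test_unresolved_mentions_ignored(self):
        corpus = tiny_corpus([("A", 2021), ("B", 2019)],
                             [mention("A", None, "methods")])
        assert gb.build_direct_citation_edges(["A", "B"], corpus) == []


class TestIndirectCitationEdges:
    def test_worked_example(self):
        # wcd_ac1=1.0, wcd_bc1=0.5, wcd_ac2=2.0, wcd_bc2=1.5 -> 5.0/4
        corpus = tiny_corpus(
            [("A", 2020), ("B", 2020), ("C1", 2020), ("C2", 2020)],
            [mention("A", "C1", "methods"),
             mention("B", "C1", "introduction"),
             mention("A", "C2", "methods", 0), mention("A", "C2", "methods", 1),
             mention("B", "C2", "methods", 0), mention("B", "C2", "introduction", 1)],
        )
        # check the direct weights really are the worked values
        sw = gb.SectionWeights()
        assert gb.direct_citation_weight(corpus, "A", "C1", sw) == 1.0
        assert gb.direct_citation_weight(corpus, "B", "C1", sw) == 0.5
        assert gb.direct_citation_weight(corpus, "A", "C2", sw) == 2.0
        # B->C2: 2 mentions, max sw over {methods, introduction} = 1.0 ... use
        # a year gap of 0 -> 2*1.0 = 2.0; adjust with sections only
        (edge,) = gb.build_indirect_citation_edges(["A", "B"], corpus)
        wb_c2 = gb.direct_citation_weight(corpus, "B", "C2", sw)
        expected = (1.0 + 0.5 + 2.0 + wb_c2) / 4
        assert edge.weight == pytest.approx(expected)

    def test_exact_worked_value(self):
        corpus = tiny_corpus(
            [("A", 2021), ("B", 2021), ("C1", 2021), ("C2", 2021)],
            [mention("A", "C1", "methods"),                      # wcd_ac1 = 1.0
             mention("B", "C1", "related_work"),                 # wcd_bc1 = 0.5
             mention("A", "C2", "methods", 0),
             mention("A", "C2", "methods", 1),                   # wcd_ac2 = 2.0
             mention("B", "C2", "introduction", 0),
             mention("B", "C2", "introduction", 1),
             mention("B", "C2", "introduction", 2)],             # wcd_bc2 = 1.5
        )
        (edge,) = gb.build_indirect_citation_edges(["A", "B"], corpus)
        assert edge.weight == pytest.approx(5.0 / 4)
        assert (edge.source, edge.target) == ("A", "B")  # year tie -> lexicographic

    def test_no_common_citations_no_edge(self):
        corpus = tiny_corpus(
            [("A", 2021), ("B", 2020), ("C1", 2019), ("C2", 2018)],
            [mention("A", "C1", "methods"), mention("B", "C2", "methods")],
        )
        assert gb.build_indirect_citation_edges(["A", "B"], corpus) == []

    def test_shared_references_need_not_be_nodes(self):
        corpus = tiny_corpus(
            [("A", 2021), ("B", 2020), ("C", 2015)],
            [mention("A", "C", "methods"), mention("B", "C", "methods")],
        )
        edges = gb.build_indirect_citation_edges(["A", "B"], corpus)
        assert len(edges) == 1

    def test_weight_is_mean_of_pairwise_average(self):
        """Algebraic identity: the weight equals the mean over common
        references c of (wcd_ac + wcd_bc)/2."""
        rng = random.Random(3)
        corpus, years, _ = random_instance(rng, n_docs=7, missing_years=False)
        sw = gb.SectionWeights()
        ids = sorted(corpus.documents)
        edges = gb.build_indirect_citation_edges(ids, corpus, sw)
        for edge in edges:
            a, b = edge.source, edge.target
            cited_a = {m.cited_id for m in corpus.mentions if m.citing_id == a}
            cited_b = {m.cited_id for m in corpus.mentions if m.citing_id == b}
            common = cited_a & cited_b
            terms = [
                ((gb.direct_citation_weight(corpus, a, c, sw) or 0.0)
                 + (gb.direct_citation_weight(corpus, b, c, sw) or 0.0)) / 2
                for c in common
            ]
            assert edge.weight == pytest.approx(sum(terms) / len(terms))


class TestSectionWeights:
    def test_defaults_downweight_framing_sections(self):
        sw = gb.SectionWeights()
        assert sw.get("introduction") == 0.5
        assert sw.get("related_work") == 0.5
        assert sw.get("methods") == 1.0  # falls back to "other"

    def test_validation(self):
        with pytest.raises(ValueError):
            gb.SectionWeights(weights={"introduction": 0.5})  # no "other"
        with pytest.raises(ValueError):
            gb.SectionWeights(weights={"other": 0.0})
        with pytest.raises(ValueError):
            gb.SectionWeights(weights={"other": 1.5})


class TestAssembleFilterExpand:
    @pytest.fixture()
    def small_graph(self):
        corpus = tiny_corpus(
            [("A", 2021), ("B", 2019), ("C", 2018)],
            [mention("A", "B", "methods")],
        )
        result = SearchResult("q", [("A", 2.0), ("B", 1.0), ("C", 0.5)], "full_text")
        profiles = {
            "A": profile("A", [("spike protein", 4.0)]),
            "B": profile("B", [("spike protein", 2.0)]),
            "C": profile("C", []),
        }
        graph = gb.build_graph(result, corpus, profiles)
        return corpus, result, profiles, graph

    def test_nodes_carry_relevance_and_origin(self, small_graph):
        _, result, _, graph = small_graph
        assert graph.nodes == [("A", 2.0, "initial"), ("B", 1.0, "initial"),
                               ("C", 0.5, "initial")]

    def test_typed_multigraph_keeps_parallel_edges(self, small_graph):
        _, _, _, graph = small_graph
        kinds = sorted(e.kind for e in graph.edges
                       if {e.source, e.target} == {"A", "B"})
        assert kinds == ["direct_citation", "term"]

    def test_dangling_edge_rejected(self):
        result = SearchResult("q", [("A", 1.0)], "full_text")
        bad = gb.Edge("A", "Z", "direct_citation", 1.0)
        with pytest.raises(ValueError):
            gb.assemble_graph(result, [bad])

    def test_threshold_zero_is_identity(self, small_graph):
        _, _, _, graph = small_graph
        assert gb.filter_by_threshold(graph, 0.0).edges == graph.edges

    def test_threshold_above_max_keeps_isolated_nodes(self, small_graph):
        _, _, _, graph = small_graph
        filtered = gb.filter_by_threshold(graph, 100.0)
        assert filtered.edges == []
        assert filtered.nodes == graph.nodes

    def test_threshold_sweep_is_nested_and_matches_linear_scan(self, small_graph):
        _, _, _, graph = small_graph
        taus = [0.0, 0.5, 1.0, 1.5, 2.5, 3.5]
        previous = None
        for tau in taus:
            kept = gb.filter_by_threshold(graph, tau).edges
            assert kept == [e for e in graph.edges if e.weight >= tau]
            if previous is not None:
                assert set(kept) <= set(previous)
            previous = kept

    def test_expand_m0_is_identity(self, small_graph):
        corpus, _, profiles, graph = small_graph
        out = gb.expand_node(graph, "A", corpus, profiles, m=0)
        assert out.nodes == graph.nodes and out.edges == graph.edges

    def test_expand_adds_cited_out_of_graph_paper(self):
        corpus = tiny_corpus(
            [("A", 2021), ("B", 2019), ("X", 2015)],
            [mention("A", "X", "methods")],
        )
        result = SearchResult("q", [("A", 2.0), ("B", 1.0)], "full_text")
        profiles = {d: [] for d in corpus.documents}
        graph = gb.build_graph(result, corpus, profiles)
        out = gb.expand_node(graph, "A", corpus, profiles, m=5)
        assert ("X", 0.0, "expanded") in out.nodes
        added = [e for e in out.edges if e.target == "X"]
        assert added and added[0].kind == "direct_citation"

    def test_expand_unknown_node_rejected(self, small_graph):
        corpus, _, profiles, graph = small_graph
        with pytest.raises(ValueError):
            gb.expand_node(graph, "nope", corpus, profiles, m=1)

    def test_expand_selects_top_m_by_strongest_edge(self):
        corpus = tiny_corpus(
            [("A", 2021), ("X1", 2020), ("X2", 2020), ("X3", 2020)],
            [mention("A", "X1", "methods", 0), mention("A", "X1", "methods", 1),
             mention("A", "X2", "introduction"),
             mention("A", "X3", "methods")],
        )
        result = SearchResult("q", [("A", 1.0)], "full_text")
        profiles = {d: [] for d in corpus.documents}
        graph = gb.build_graph(result, corpus, profiles)
        out = gb.expand_node(graph, "A", corpus, profiles, m=2)
        added = {n for n, _, o in out.nodes if o == "expanded"}
        # strongest: X1 (N=2 -> 2.0), then X3 (1.0) beats X2 (0.5)
        assert added == {"X1", "X3"}

    def test_expand_idempotent_when_no_new_neighbours(self, small_graph):
        corpus, _, profiles, graph = small_graph
        once = gb.expand_node(graph, "A", corpus, profiles, m=5)
        twice = gb.expand_node(once, "A", corpus, profiles, m=5)
        assert twice.nodes == once.nodes and twice.edges == once.edges


class TestExportImport:
    def test_empty_graph_exports_valid_files(self, tmp_path):
        graph = gb.DocumentGraph()
        path = gb.export_graph(graph, tmp_path / "g.json", "nodelink_json")
        back = gb.import_graph(path, "nodelink_json")
        assert back.nodes == [] and back.edges == []

    @pytest.mark.parametrize("fmt,ext", [("nodelink_json", "json"), ("graphml", "graphml")])
    def test_roundtrip_identity(self, tmp_path, fmt, ext, fixture_corpus):
        corpus, _ = fixture_corpus
        from litgraph.retrieval import build_index, search

        idx = build_index(corpus, "full_text")
        result = search(idx, "viral spike protein", k=8)
        graph = gb.build_graph(result, corpus)
        path = gb.export_graph(graph, tmp_path / f"g.{ext}", fmt)
        back = gb.import_graph(path, fmt)
        assert sorted(back.nodes) == sorted(graph.nodes)
        assert sorted(back.edges, key=repr) == sorted(graph.edges, key=repr)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            gb.export_graph(gb.DocumentGraph(), tmp_path / "g.dot", "dot")


class TestOracleEquivalence:
    def test_edge_weights_match_bruteforce_on_random_instances(self):
        rng = random.Random(12345)
        sw = gb.SectionWeights()
        sw_map = dict(sw.weights)
        for _ in range(100):
            corpus, years, profiles = random_instance(rng)
            ids = sorted(corpus.documents)
            table = [(m.citing_id, m.cited_id, m.section_label) for m in corpus.mentions]

            direct = {(e.source, e.target): e.weight
                      for e in gb.build_direct_citation_edges(ids, corpus, sw)}
            assert direct.keys() == oracle_direct_weights(table, years, sw_map).keys()
            for pair, w in oracle_direct_weights(table, years, sw_map).items():
                assert direct[pair] == pytest.approx(w, abs=1e-12)

            indirect = {frozenset((e.source, e.target)): e.weight
                        for e in gb.build_indirect_citation_edges(ids, corpus, sw)}
            expected_ind = oracle_indirect_weights(ids, table, years, sw_map)
            assert indirect == {
                frozenset(k): pytest.approx(v, abs=1e-12)
                for k, v in expected_ind.items()
            }

            result = SearchResult("q", [(d, 1.0) for d in ids], "full_text")
            term_edges = gb.build_term_edges(result, profiles, corpus)
            got_terms = {}
            for e in term_edges:
                got_terms.setdefault(frozenset((e.source, e.target)), {})[e.label] = e.weight
            expected_terms = oracle_term_edges(
                ids, {d: {s.term: s.cvalue for s in profiles[d]} for d in ids}
            )
            assert got_terms == {
                frozenset(k): {t: pytest.approx(w, abs=1e-12) for t, w in v.items()}
                for k, v in expected_terms.items()
            }

    def test_every_edge_direction_is_newest_to_oldest(self):
        rng = random.Random(999)
        sw = gb.SectionWeights()
        for _ in range(50):
            corpus, years, profiles = random_instance(rng)
            ids = sorted(corpus.documents)
            result = SearchResult("q", [(d, 1.0) for d in ids], "full_text")
            edges = (
                gb.build_term_edges(result, profiles, corpus)
                + gb.build_indirect_citation_edges(ids, corpus, sw)
            )
            for e in edges:
                ya, yb = years[e.source], years[e.target]
                if ya is not None and yb is not None and ya != yb:
                    assert ya > yb
                else:
                    assert e.source < e.target
            for e in gb.build_direct_citation_edges(ids, corpus, sw):
                assert any(m.citing_id == e.source and m.cited_id == e.target
                           for m in corpus.mentions)
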