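"""Grammar, filter semantics, map execution and attribute selection."""

import itertools
import random

import pytest

from xrefdb.model import EntryPayload
from xrefdb.querylang import (
    And,
    BoolAttr,
    Compare,
    Contains,
    FilterEvalError,
    FilterStep,
    MapStep,
    QuerySemanticError,
    QuerySyntaxError,
    SelectorError,
    Within,
    eval_filter,
    execute_mapping,
    map_step,
    parse_query,
    select_attrs,
)

UC1 = 'map(transcript).map(ensembl).map(go).filter(go.type=="molecular_function")'
UC2 = ('map(ensembl).filter(ensembl.within(100000000,101000000) && '
       'ensembl.seq_region=="X").map(uniprot).filter(uniprot.reviewed)')
UC3 = 'map(taxchild).map(ensembl).filter(ensembl.start<10000&&ensembl.description.contains("SopD"))'


def E(**attrs) -> EntryPayload:
    return EntryPayload(1, attrs.pop("_id", "X"), attrs)


class TestParser:
    def test_probe_to_go_chain(self):
        q = parse_query(UC1)
        assert q.steps == (
            MapStep("transcript"),
            MapStep("ensembl"),
            MapStep("go"),
            FilterStep(Compare("go", "type", "==", "molecular_function")),
        )

    def test_range_and_boolean_chain(self):
        q = parse_query(UC2)
        maps = [s for s in q.steps if isinstance(s, MapStep)]
        filters = [s for s in q.steps if isinstance(s, FilterStep)]
        assert [m.target for m in maps] == ["ensembl", "uniprot"]
        assert filters[0].expr == And(
            Within("ensembl", 100000000, 101000000),
            Compare("ensembl", "seq_region", "==", "X"),
        )
        assert filters[1].expr == BoolAttr("uniprot", "reviewed")

    def test_empty_map_target_position(self):
        with pytest.raises(QuerySyntaxError) as err:
            parse_query("map()")
        assert err.value.position == 4

    @pytest.mark.parametrize("bad", ["", "filter(go.type==1)", "map(go).map()", "map(go)extra",
                                     "map(go).filter(go.type=)"])
    def test_malformed(self, bad):
        with pytest.raises(QuerySyntaxError):
            parse_query(bad)

    def test_filter_prefix_must_match_active_dataset(self):
        with pytest.raises(QuerySemanticError):
            parse_query('map(go).filter(ensembl.start<5)')
        # relation labels activate their underlying dataset
        q = parse_query('map(taxchild).filter(taxonomy.rank=="species")')
        assert isinstance(q.steps[1], FilterStep)

    @pytest.mark.parametrize("text", [UC1, UC2, UC3,
                                      'map(go).filter(go.name.contains("x") || go.type!="y")'])
    def test_reserialization_round_trips(self, text):
        q = parse_query(text)
        assert parse_query(q.to_text()) == q


class TestFilterSemantics:
    def test_within_strict_bounds(self):
        assert eval_filter(Within("ensembl", 100000000, 101000000),
                           E(start=100500000, end=100600000))
        assert not eval_filter(Within("ensembl", 100000000, 101000000),
                               E(start=100000000, end=100600000))

    def test_within_equals_expanded_form_on_grid(self):
        a, b = 1000, 2000
        for s, e in itertools.product([a - 1, a, a + 1], [b - 1, b, b + 1]):
            entry = E(start=s, end=e)
            expanded = s > a and e < b
            assert eval_filter(Within("d", a, b), entry) == expanded

    def test_contains_and_strict_less(self):
        assert eval_filter(Contains("d", "description", "SopD"),
                           E(description="Secreted effector protein SopD"))
        assert not eval_filter(Contains("d", "description", "sopd"),
                               E(description="Secreted effector protein SopD"))
        assert not eval_filter(Compare("d", "start", "<", 10000), E(start=10000))

    def test_bool_attr(self):
        assert eval_filter(BoolAttr("u", "reviewed"), E(reviewed=True))
        assert not eval_filter(BoolAttr("u", "reviewed"), E(reviewed=False))
        assert not eval_filter(BoolAttr("u", "reviewed"), E())

    def test_missing_attribute_is_false_not_error(self):
        assert not eval_filter(Compare("d", "nope", "<", 5), E(start=1))
        assert not eval_filter(Within("d", 1, 10), E())

    def test_numeric_coercion(self):
        assert eval_filter(Compare("d", "start", ">", 5), E(start="7"))
        assert not eval_filter(Compare("d", "start", "==", 5), E(start="abc"))

    def test_type_mismatch_error(self):
        with pytest.raises(FilterEvalError):
            eval_filter(Compare("d", "start", "<", "10000"), E(start=5))

    def test_boolean_algebra(self, universe):
        _handle, graph, _files = universe
        exprs = [
            Compare("ensembl", "start", "<", 2_000_000),
            Contains("ensembl", "description", "protein"),
            Compare("ensembl", "strand", "==", "+"),
        ]
        entries = [EntryPayload(1, graph.identifiers[k], graph.nodes[k])
                   for k in graph.nodes if k.dataset == "ensembl"]
        assert entries
        for a, b in itertools.permutations(exprs, 2):
            for entry in entries:
                assert eval_filter(And(a, b), entry) == (eval_filter(a, entry) and eval_filter(b, entry))
                assert eval_filter(Or(a, b), entry) == (eval_filter(a, entry) or eval_filter(b, entry))


from xrefdb.querylang import Or  # noqa: E402


class TestSelectAttrs:
    def test_indexed_name(self):
        entry = E(names=["Tetraspanin-6", "TSPAN6"])
        assert select_attrs(entry, "names[1]") == ["Tetraspanin-6"]

    def test_multi_column(self):
        entry = E(strand="+", start=2525, end=3484)
        assert select_attrs(entry, "strand,start,end") == ["+", 2525, 3484]

    def test_out_of_range_empty_marker(self):
        entry = E(names=["a", "b"])
        assert select_attrs(entry, "names[9]") == ["-"]
        assert select_attrs(entry, "absent") == ["-"]

    @pytest.mark.parametrize("bad", ["names[0]", "na me", "names[x]", ",,"])
    def test_malformed_selector(self, bad):
        with pytest.raises(SelectorError):
            select_attrs(E(), bad)


class TestMapStep:
    def test_taxchild_children(self, worked_example):
        handle, graph, _files = worked_example
        from xrefdb.store import lookup

        root = lookup(handle, "59201")
        children = map_step(handle, root, "taxchild")
        assert sorted(c.identifier for c in children) == ["1249525", "465517", "595", "984254"]

    def test_no_matching_xrefs_empty(self, worked_example_store):
        from xrefdb.store import lookup

        probe = lookup(worked_example_store, "202763_at")
        assert map_step(worked_example_store, probe, "go") == []

    def test_unknown_target(self, worked_example_store):
        from xrefdb.querylang import UnknownDatasetError

        with pytest.raises(UnknownDatasetError) as err:
            map_step(worked_example_store, [], "nope")
        assert "taxchild" in str(err.value)

    def test_random_hops_vs_graph(self, universe):
        handle, graph, _files = universe
        from xrefdb.store import lookup

        rng = random.Random(13)
        keys = sorted(graph.nodes, key=lambda k: (k.dataset, k.norm_id))
        for _ in range(300):
            key = rng.choice(keys)
            labels = sorted({lab for lab, _ in graph.edges[key]} or {"go"})
            target = rng.choice(labels)
            entries = lookup(handle, key.norm_id)
            entries = [e for e in entries if e.dataset_id == handle.registry.get(key.dataset).numeric_id]
            got = {e.identifier for e in map_step(handle, entries, target)}
            expect = {graph.identifiers[dst] for dst in graph.neighbors(key, target)}
            assert got == expect, (key, target)

    def test_transitive_taxchild_closure(self, worked_example_store):
        from xrefdb.store import lookup

        root = lookup(worked_example_store, "590")
        direct = {e.identifier for e in map_step(worked_example_store, root, "taxchild")}
        closure = {e.identifier
                   for e in map_step(worked_example_store, root, "taxchild", transitive_taxchild=True)}
        assert direct == {"59201", "9606", "28901"} - {"9606"}
        assert closure == direct | {"595", "984254", "465517", "1249525"}


class TestExecuteMapping:
    def test_unresolved_term_zero_rows(self, worked_example_store):
        result = execute_mapping(worked_example_store, "NOT_A_TERM", "map(go)")
        assert result.rows == []

    def test_source_restriction(self, worked_example_store):
        # CASP8 resolves in both hgnc (symbol keyword) and ensembl (gene name)
        all_ds = execute_mapping(worked_example_store, "CASP8", "map(go)")
        hgnc_only = execute_mapping(worked_example_store, "CASP8", "map(go)", source="hgnc")
        assert {r.mapping_id for r in all_ds.rows} and hgnc_only.rows == []

    def test_unknown_source_errors(self, worked_example_store):
        from xrefdb.querylang import UnknownDatasetError

        with pytest.raises(UnknownDatasetError):
            execute_mapping(worked_example_store, "CASP8", "map(go)", source="nope")

    def test_filter_never_enlarges_rows(self, universe):
        handle, graph, _files = universe
        from xrefdb import fixtures

        rng = random.Random(29)
        checked = 0
        for term, qtext, source in fixtures.random_queries(graph, rng, 200):
            q = parse_query(qtext)
            without = tuple(s for s in q.steps if isinstance(s, MapStep))
            full = execute_mapping(handle, term, q, source=source, page_size=10**6)
            bare = execute_mapping(
                handle, term, type(q)(steps=without), source=source, page_size=10**6
            )
            full_set = {(r.input_term, r.mapping_id) for r in full.rows}
            bare_set = {(r.input_term, r.mapping_id) for r in bare.rows}
            assert full_set <= bare_set
            checked += 1
        assert checked == 200

    def test_paging_completeness(self, worked_example_store):
        q = UC1
        unpaged = execute_mapping(
            worked_example_store, "202763_at,209310_s_at", q,
            source="affy_hg_u133_plus_2", page_size=10**6,
        )
        for size in (1, 2, 7, 200):
            collected = []
            token = None
            while True:
                page = execute_mapping(
                    worked_example_store, "202763_at,209310_s_at", q,
                    source="affy_hg_u133_plus_2", page_size=size, token=token,
                )
                collected.extend(r.as_tuple() for r in page.rows)
                if page.next_token is None:
                    break
                token = page.next_token
            assert collected == [r.as_tuple() for r in unpaged.rows]

    def test_oracle_equivalence_500_random_queries(self, universe):
        handle, graph, _files = universe
        from xrefdb import fixtures

        rng = random.Random(42)
        nonempty = 0
        for term, qtext, source in fixtures.random_queries(graph, rng, 500):
            expect = {(t, m) for t, m in graph.oracle_map(term, qtext, source)}
            rows = execute_mapping(handle, term, qtext, source=source, page_size=10**6).rows
            got = {(r.input_term, r.mapping_id) for r in rows}
            assert got == expect, (term, qtext, source)
            nonempty += bool(expect)
        assert nonempty > 100  # the query generator must exercise real chains
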