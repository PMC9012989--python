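import json
import re

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thermoapos as ta
from thermoapos.apos import mean_attribute_depth
from thermoapos.errors import LookupError_, ParameterError
from thermoapos.granulation import FormalContext


def ctx_from_rows(rows, attrs=None, objects=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=int))
    attrs = attrs or [f"a{j}" for j in range(rows.shape[1])]
    objects = objects or [f"o{i}" for i in range(rows.shape[0])]
    return FormalContext(pd.DataFrame(rows, index=objects, columns=attrs))


class TestAttributeRanking:
    def test_coverage_descending_with_lexicographic_ties(self):
        ctx = ctx_from_rows(
            [[1, 1, 1], [1, 0, 1], [1, 0, 1]], attrs=["a", "b", "c"]
        )  # coverage a:3, b:1, c:3
        assert ta.attribute_ranking(ctx) == ("a", "c", "b")

    def test_equal_coverage_is_pure_lexicographic(self):
        ctx = ctx_from_rows([[1, 1, 1]], attrs=["b", "c", "a"])
        assert ta.attribute_ranking(ctx) == ("a", "b", "c")

    def test_uncovered_attribute_excluded(self):
        ctx = ctx_from_rows([[1, 0], [1, 0]], attrs=["a", "dead"])
        assert ta.attribute_ranking(ctx) == ("a",)


class TestTrieConstruction:
    def test_single_object_single_branch(self):
        ctx = ctx_from_rows([[1, 1]], attrs=["a", "b"])
        graph = ta.build_apos(ctx)
        branch = ta.query_branch(graph, "o0")
        assert branch.path == ("a", "b")  # equal coverage: lexicographic

    def test_universal_attribute_heads_every_branch(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 2, size=(6, 5))
        rows[:, 2] = 1  # attribute a2 covers everything
        graph = ta.build_apos(ctx_from_rows(rows))
        for branch in graph.branches:
            if branch.path:
                assert branch.path[0] == "a2"

    def test_identical_intents_share_a_branch(self):
        ctx = ctx_from_rows([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        graph = ta.build_apos(ctx)
        assert graph.n_leaves == 2
        assert ta.query_branch(graph, "o0") == ta.query_branch(graph, "o1")

    def test_empty_intent_object_warns_and_sits_at_root(self):
        ctx = ctx_from_rows([[0, 0], [1, 1]])
        with pytest.warns(UserWarning):
            graph = ta.build_apos(ctx)
        assert ta.query_branch(graph, "o0").path == ()

    def test_unknown_object_lookup(self):
        graph = ta.build_apos(ctx_from_rows([[1]]))
        with pytest.raises(LookupError_):
            ta.query_branch(graph, "ghost")

    def test_branch_reconstructs_context_row(self):
        rng = np.random.default_rng(5)
        ctx = ctx_from_rows(rng.integers(0, 2, size=(8, 6)))
        graph = ta.build_apos(ctx)
        for obj in ctx.objects:
            assert set(ta.query_branch(graph, obj).path) == set(ctx.intent(obj))

    @pytest.mark.filterwarnings("ignore:object .* empty intent")
    @pytest.mark.parametrize("seed", range(10))
    def test_leaf_count_equals_distinct_intents(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7), rng.integers(1, 7)
        rows = rng.integers(0, 2, size=(n, m))
        graph = ta.build_apos(ctx_from_rows(rows))
        brute = {tuple(r) for r in rows}
        assert graph.n_leaves == len(brute)

    @pytest.mark.filterwarnings("ignore:object .* empty intent")
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_leaf_count_property(self, n, m, seed):
        rows = np.random.default_rng(seed).integers(0, 2, size=(n, m))
        graph = ta.build_apos(ctx_from_rows(rows))
        assert graph.n_leaves == len({tuple(r) for r in rows})


class TestStructuralInvariants:
    @pytest.mark.filterwarnings("ignore:object .* empty intent")
    @pytest.mark.parametrize("seed", range(5))
    def test_coverage_non_increasing_along_paths(self, seed):
        rng = np.random.default_rng(seed)
        ctx = ctx_from_rows(rng.integers(0, 2, size=(10, 8)))
        graph = ta.build_apos(ctx)
        for branch in graph.branches:
            covs = [graph.nodes[branch.path[: i + 1]].coverage for i in range(len(branch.path))]
            assert all(a >= b for a, b in zip(covs, covs[1:]))

    def test_union_of_branches_reconstructs_context(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, size=(7, 6))
        rows[0, :] = 1  # ensure no all-zero warning path is hit: o0 covers all
        ctx = ctx_from_rows(np.where(rows.sum(axis=1, keepdims=True) == 0, 1, rows))
        graph = ta.build_apos(ctx)
        for obj in ctx.objects:
            rebuilt = {a: 0 for a in ctx.attributes}
            for a in ta.query_branch(graph, obj).path:
                rebuilt[a] = 1
            assert list(rebuilt.values()) == list(ctx.table.loc[obj])

    def test_extent_containment_order(self):
        ctx = ctx_from_rows([[1, 1, 0], [1, 0, 0], [1, 1, 1]], attrs=["a", "b", "c"])
        graph = ta.build_apos(ctx)
        assert "a" in graph.order["b"]      # extent(b) ⊆ extent(a)
        assert "b" not in graph.order["a"]
        assert graph.order["c"] == {"a", "b", "c"}


class TestLevelReport:
    def test_universal_attribute_only_at_level_one(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 2, size=(8, 5))
        rows[:, 0] = 1
        rows[rows.sum(axis=1) == 1, 1] = 1  # no singleton intents of a0 alone needed
        graph = ta.build_apos(ctx_from_rows(rows))
        report = ta.level_report(graph)
        assert "a0" in report[1]
        for lvl, attrs in report.items():
            if lvl != 1:
                assert "a0" not in attrs

    def test_common_attributes_sit_shallower_than_rare_ones(self):
        """Cohort where face-side high attributes are common and chest-side
        high attributes are rare: the mining signal is that the common ones
        occupy strictly shallower levels on average."""
        rng = np.random.default_rng(7)
        n = 30
        face = rng.random((n, 2)) < 0.9
        chest = rng.random((n, 2)) < 0.15
        filler = rng.random((n, 4)) < 0.5
        rows = np.column_stack([face, chest, filler]).astype(int)
        ctx = ctx_from_rows(
            rows, attrs=["face1-H", "face2-H", "chest1-H", "chest2-H", "x1", "x2", "x3", "x4"]
        )
        graph = ta.build_apos(ctx)
        face_depth = np.mean([mean_attribute_depth(graph, a) for a in ("face1-H", "face2-H")])
        chest_depth = np.mean([mean_attribute_depth(graph, a) for a in ("chest1-H", "chest2-H")])
        assert face_depth < chest_depth

    def test_trivial_context_report(self):
        graph = ta.build_apos(ctx_from_rows([[1]], attrs=["only"]))
        assert ta.level_report(graph) == {1: ("only",)}


class TestExport:
    @pytest.fixture()
    def graph(self):
        rng = np.random.default_rng(4)
        return ta.build_apos(ctx_from_rows(rng.integers(0, 2, size=(5, 4))))

    def test_json_round_trip_preserves_nodes_and_edges(self, graph, tmp_path):
        path = tmp_path / "g.json"
        ta.export_graph(graph, path, "json")
        payload = json.loads(path.read_text())
        g = graph.to_networkx()
        assert {n["id"] for n in payload["nodes"]} == set(g.nodes)
        assert {tuple(e) for e in payload["edges"]} == set(g.edges)

    def test_dot_output_is_well_formed(self, graph, tmp_path):
        path = tmp_path / "g.dot"
        ta.export_graph(graph, path, "dot")
        text = path.read_text()
        assert text.startswith("digraph")
        assert text.count("{") == text.count("}") == 1
        declared = set(re.findall(r'^\s*"([^"]+)" \[', text, flags=re.M))
        for u, v in re.findall(r'^\s*"([^"]+)" -> "([^"]+)";', text, flags=re.M):
            assert u in declared and v in declared

    def test_graphml_parses_back(self, graph, tmp_path):
        path = tmp_path / "g.graphml"
        ta.export_graph(graph, path, "graphml")
        back = nx.read_graphml(path)
        g = graph.to_networkx()
        assert set(back.nodes) == set(g.nodes)
        assert set(back.edges) == set(g.edges)

    def test_single_branch_is_a_chain(self, tmp_path):
        graph = ta.build_apos(ctx_from_rows([[1, 1, 1]]))
        g = graph.to_networkx()
        assert nx.is_directed_acyclic_graph(g)
        degrees = [d for _, d in g.out_degree()]
        assert sorted(degrees) == [0, 1, 1, 1]

    def test_unknown_format(self, graph, tmp_path):
        with pytest.raises(ParameterError):
            ta.export_graph(graph, tmp_path / "x", "svg")
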