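"""Attribute partial order structure (APOS) knowledge graphs.

An APOS diagram organizes a binary formal context into a layered graph
following four principles: attributes covering more objects sit higher;
similar objects sit close together; higher nodes are more universal, lower
nodes more specific; and each branch spells out the full attribute set
(intent) of one object. This module realizes those principles as a
coverage-ordered prefix trie: attributes are totally ordered by descending
coverage (ties lexicographic), every object's intent — sorted in that order —
is inserted as a root-to-leaf path, and objects with identical intents share
a branch. The extent-containment partial order (a <= b iff every object with
a also has b) is kept alongside as the structure's namesake relation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx

from .errors import LookupError_, ParameterError
from .granulation import FormalContext

__all__ = [
    "AttributeNode",
    "ObjectBranch",
    "APOSGraph",
    "attribute_ranking",
    "build_apos",
    "query_branch",
    "level_report",
    "export_graph",
]

ROOT = ()  # trie root: the empty attribute path


@dataclass(frozen=True)
class AttributeNode:
    """One placed attribute node: a trie position and its annotations."""

    path: tuple[str, ...]      # attribute path from the root, incl. itself
    attribute: str
    level: int                 # depth in the diagram (root children = 1)
    coverage: int              # objects possessing the attribute, context-wide
    extent: tuple              # those objects


@dataclass(frozen=True)
class ObjectBranch:
    """One root-to-leaf branch: the ordered intent of its object(s)."""

    objects: tuple
    path: tuple[str, ...]


@dataclass
class APOSGraph:
    """Coverage-ordered intent trie plus the extent-containment order."""

    nodes: dict[tuple, AttributeNode]
    children: dict[tuple, list]                 # path -> ordered child paths
    leaves: dict[tuple, tuple]                  # leaf path -> object ids
    branch_of: dict[object, tuple]              # object id -> its leaf path
    ranking: tuple[str, ...]                    # coverage-descending order
    order: dict[str, frozenset]                 # attr -> attrs it is <= of
    context: FormalContext

    @property
    def branches(self) -> list[ObjectBranch]:
        return [ObjectBranch(objs, path) for path, objs in sorted(self.leaves.items())]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node("root", level=0)
        for path, node in sorted(self.nodes.items()):
            g.add_node(
                "/".join(path),
                attribute=node.attribute,
                level=node.level,
                coverage=node.coverage,
            )
        for parent, kids in self.children.items():
            pname = "/".join(parent) if parent else "root"
            for kid in kids:
                g.add_edge(pname, "/".join(kid))
        for path, objs in self.leaves.items():
            g.nodes["/".join(path) if path else "root"]["objects"] = ",".join(map(str, objs))
        return g


def attribute_ranking(context: FormalContext) -> tuple[str, ...]:
    """Total attribute order: coverage descending, ties lexicographic by
    name; attributes covering no object are dropped."""
    cov = context.table.sum(axis=0)
    present = [a for a in context.attributes if cov[a] > 0]
    return tuple(sorted(present, key=lambda a: (-int(cov[a]), a)))


def build_apos(context: FormalContext) -> APOSGraph:
    """Insert every object's ranked intent into the trie and compute the
    extent-containment order.

    An object with an empty intent keeps a root-only branch and triggers a
    warning — it carries no attribute information but must not vanish.
    """
    ranking = attribute_ranking(context)
    rank_index = {a: i for i, a in enumerate(ranking)}
    extents = {a: frozenset(context.extent(a)) for a in ranking}

    nodes: dict[tuple, AttributeNode] = {}
    children: dict[tuple, list] = {ROOT: []}
    leaves: dict[tuple, tuple] = {}
    branch_of: dict[object, tuple] = {}
    leaf_members: dict[tuple, list] = {}

    for obj in context.objects:
        intent = sorted(context.intent(obj), key=rank_index.__getitem__)
        if not intent:
            warnings.warn(f"object {obj!r} has an empty intent; placed at the root")
        path = ROOT
        for attr in intent:
            nxt = path + (attr,)
            if nxt not in nodes:
                nodes[nxt] = AttributeNode(
                    path=nxt,
                    attribute=attr,
                    level=len(nxt),
                    coverage=len(extents[attr]),
                    extent=tuple(sorted(map(str, extents[attr]))),
                )
                children.setdefault(path, []).append(nxt)
                children[nxt] = []
            path = nxt
        leaf_members.setdefault(path, []).append(obj)
        branch_of[obj] = path
    leaves = {path: tuple(objs) for path, objs in leaf_members.items()}

    order = {
        a: frozenset(b for b in ranking if extents[a] <= extents[b])
        for a in ranking
    }
    return APOSGraph(
        nodes=nodes,
        children=children,
        leaves=leaves,
        branch_of=branch_of,
        ranking=ranking,
        order=order,
        context=context,
    )


def query_branch(graph: APOSGraph, obj) -> ObjectBranch:
    """The branch of one object; its path set equals the object's intent."""
    if obj not in graph.branch_of:
        raise LookupError_(f"object {obj!r} not in the context")
    path = graph.branch_of[obj]
    return ObjectBranch(objects=graph.leaves[path], path=path)


def level_report(graph: APOSGraph) -> dict[int, tuple[str, ...]]:
    """For each depth, the sorted set of attributes placed there.

    Reading the report top-down mirrors how rules are read off the diagram:
    attributes confined to the top levels are near-universal in the cohort,
    attributes first appearing deep are specific to few subjects.
    """
    by_level: dict[int, set] = {}
    for node in graph.nodes.values():
        by_level.setdefault(node.level, set()).add(node.attribute)
    return {lvl: tuple(sorted(attrs)) for lvl, attrs in sorted(by_level.items())}


def mean_attribute_depth(graph: APOSGraph, attribute: str) -> float:
    """Mean trie depth over all placements of one attribute (inf if absent)."""
    depths = [n.level for n in graph.nodes.values() if n.attribute == attribute]
    return sum(depths) / len(depths) if depths else float("inf")


def _to_dot(g: nx.DiGraph) -> str:
    lines = ["digraph APOS {", "  rankdir=TB;", '  node [shape=box];']
    for name, data in g.nodes(data=True):
        label = data.get("attribute", "root")
        cov = data.get("coverage")
        text = f"{label}\\n(cov {cov})" if cov is not None else label
        lines.append(f'  "{name}" [label="{text}"];')
    for u, v in g.edges():
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(graph: APOSGraph, path, fmt: str = "json") -> None:
    """Lossless export of nodes/edges with coverage and level annotations.

    Formats: ``json`` (native, round-trips node/edge sets), ``dot``
    (Graphviz text), ``graphml``.
    """
    g = graph.to_networkx()
    fmt = fmt.lower()
    if fmt == "json":
        payload = {
            "nodes": [
                {"id": n, **{k: v for k, v in d.items()}} for n, d in sorted(g.nodes(data=True))
            ],
            "edges": sorted([u, v] for u, v in g.edges()),
            "ranking": list(graph.ranking),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write(_to_dot(g))
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ParameterError(f"unknown export format {fmt!r}; use json, dot, or graphml")
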