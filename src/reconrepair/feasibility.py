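"""Temporal feasibility of a DTL-scenario via a directed constraint graph.

A reconciliation of undated trees is temporally feasible iff the internal
host nodes can be dated consistently with every event it implies.  That
holds iff the *temporal feasibility graph* is acyclic.  Vertices are the
internal nodes of both trees plus a single sink representing all leaves;
an edge (u, v) means "u must be dated before v".  Construction rules:

1. vertices: internal host nodes, internal parasite nodes, leaf sink;
2. a tree edge parent -> child (both internal) in either tree;
3. an edge v -> sink for every internal node that is a parent of a leaf;
4. per gene node g mapped to species node s:
   (a) speciation — g is *identified* with s (merged into the species
       vertex; a speciation happens exactly at its species divergence);
   (b) duplication — edges pa(s) -> g (omitted when s is the host root)
       and g -> s: the duplication happens strictly inside the edge above s;
   (c) transfer with landing site s' — edges pa(s) -> g, g -> s,
       pa(s') -> g, g -> s': takeoff and landing are contemporaneous, so
       the event lies strictly inside both host edges.

Any endpoint that is a host leaf is redirected to the sink; edges between
identified vertices are re-targeted to their representatives; parallel
edges collapse (set semantics) but remember every rule that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx

from .scenario import (
    DTLScenario,
    DUPLICATION,
    InvalidScenarioError,
    ProblemInstance,
    SPECIATION,
    validate_scenario,
)
from .trees import RootedBinaryTree

__all__ = [
    "LEAF_SINK",
    "FeasibilityGraph",
    "build_feasibility_graph",
    "is_feasible",
    "nodes_on_cycles",
    "feasible_dating",
    "InfeasibleScenarioError",
]

LEAF_SINK = "leaf-sink"

# vertex keys: ("S", name) for internal host nodes, ("G", name) for
# non-identified internal parasite nodes, LEAF_SINK for the sink.
Vertex = object


class InfeasibleScenarioError(ValueError):
    pass


@dataclass
class FeasibilityGraph:
    """The constraint graph plus the speciation identification map."""

    graph: nx.DiGraph
    identification: Dict[str, Vertex]  # gene node -> representative vertex
    species_vertices: Tuple[Vertex, ...]

    def representative(self, gene_node: str) -> Vertex:
        """Vertex carrying gene node ``g`` (its species vertex if identified)."""
        return self.identification.get(gene_node, ("G", gene_node))

    def edge_rules(self, u: Vertex, v: Vertex) -> Set[str]:
        return self.graph.edges[u, v]["rules"]

    def to_dot(self) -> str:
        """Render as Graphviz DOT text (vertex kind encoded in the shape)."""
        lines = ["digraph feasibility {"]

        def name(v: Vertex) -> str:
            if v == LEAF_SINK:
                return "leaves"
            kind, label = v
            return f"{kind}_{label}"

        for v in self.graph.nodes:
            shape = "box" if isinstance(v, tuple) and v[0] == "S" else (
                "point" if v == LEAF_SINK else "ellipse")
            lines.append(f'  {name(v)} [shape={shape}];')
        for u, v, data in self.graph.edges(data=True):
            rules = ",".join(sorted(data["rules"]))
            lines.append(f'  {name(u)} -> {name(v)} [label="{rules}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_feasibility_graph(
    inst: ProblemInstance, sc: DTLScenario
) -> FeasibilityGraph:
    """Construct the temporal feasibility graph of a valid scenario."""
    violations = validate_scenario(inst, sc)
    if violations:
        raise InvalidScenarioError(violations)

    S, G = inst.host, inst.parasite
    identification: Dict[str, Vertex] = {}
    for g in G.internal_nodes:
        if sc.events[g] == SPECIATION:
            identification[g] = ("S", sc.mapping[g])

    def species_vertex(s: str) -> Vertex:
        return LEAF_SINK if S.is_leaf(s) else ("S", s)

    def gene_vertex(g: str) -> Vertex:
        return identification.get(g, ("G", g))

    graph = nx.DiGraph()
    graph.add_node(LEAF_SINK)
    for s in S.internal_nodes:
        graph.add_node(("S", s))
    for g in G.internal_nodes:
        graph.add_node(gene_vertex(g))

    def add_edge(u: Vertex, v: Vertex, rule: str) -> None:
        if u == v:
            # cannot arise from a valid scenario; guard against silent cycles
            raise AssertionError(f"self-loop at {u!r} from rule {rule}")
        if graph.has_edge(u, v):
            graph.edges[u, v]["rules"].add(rule)
        else:
            graph.add_edge(u, v, rules={rule})

    # rules 2 and 3: ancestry within each tree, leaves to the sink
    for s in S.internal_nodes:
        for child in S.children_of(s):
            if S.is_leaf(child):
                add_edge(("S", s), LEAF_SINK, "leaf")
            else:
                add_edge(("S", s), ("S", child), "tree")
    for g in G.internal_nodes:
        for child in G.children_of(g):
            if G.is_leaf(child):
                add_edge(gene_vertex(g), LEAF_SINK, "leaf")
            else:
                u, v = gene_vertex(g), gene_vertex(child)
                if u != v:
                    add_edge(u, v, "tree")
                # identical representatives cannot occur: a speciation's
                # children map strictly below it, so parent and child gene
                # nodes are never identified with the same species vertex.

    # rule 4: event placement constraints
    for g in G.internal_nodes:
        s = sc.mapping[g]
        event = sc.events[g]
        if event == SPECIATION:
            continue  # rule 4a: handled by identification
        gv = gene_vertex(g)
        if event == DUPLICATION:
            parent = S.parent_of(s)
            if parent is not None:
                add_edge(("S", parent), gv, "4b")
            add_edge(gv, species_vertex(s), "4b")
        else:  # transfer
            site = sc.landing[g]
            add_edge(("S", S.parent_of(s)), gv, "4c")
            add_edge(gv, species_vertex(s), "4c")
            add_edge(("S", S.parent_of(site)), gv, "4c")
            add_edge(gv, species_vertex(site), "4c")

    return FeasibilityGraph(
        graph=graph,
        identification=identification,
        species_vertices=tuple(("S", s) for s in S.internal_nodes),
    )


def is_feasible(fg: FeasibilityGraph) -> Tuple[bool, Optional[List[Vertex]]]:
    """Acyclicity test; when infeasible, also return one cycle's vertices."""
    if nx.is_directed_acyclic_graph(fg.graph):
        return True, None
    cycle_edges = nx.find_cycle(fg.graph)
    return False, [u for u, _ in cycle_edges]


def nodes_on_cycles(fg: FeasibilityGraph) -> Set[str]:
    """Gene nodes whose representative vertex lies on some directed cycle.

    A vertex is cycle-bound iff its strongly connected component has at
    least two vertices (the graph has no self-loops).  Identified
    speciation nodes are reported under their gene identity.
    """
    on_cycle: Set[Vertex] = set()
    for comp in nx.strongly_connected_components(fg.graph):
        if len(comp) >= 2:
            on_cycle |= comp
    result: Set[str] = set()
    for g, rep in fg.identification.items():
        if rep in on_cycle:
            result.add(g)
    for v in on_cycle:
        if isinstance(v, tuple) and v[0] == "G":
            result.add(v[1])
    return result


def feasible_dating(
    fg: FeasibilityGraph, host: RootedBinaryTree
) -> List[str]:
    """A feasible dating: internal host nodes in a valid temporal order.

    Restriction to the host's internal nodes of a topological order of the
    feasibility graph; every node precedes its children.  Deterministic:
    among simultaneously available vertices the one with the smallest host
    post-order index (species), then gene identity, is emitted first.
    """
    if not nx.is_directed_acyclic_graph(fg.graph):
        raise InfeasibleScenarioError("infeasible scenario: feasibility graph is cyclic")

    def sort_key(v: Vertex):
        if v == LEAF_SINK:
            return (2, 0, "")
        kind, label = v
        if kind == "S":
            return (0, host.postorder_index(label), label)
        return (1, 0, label)

    order = nx.lexicographical_topological_sort(fg.graph, key=sort_key)
    return [v[1] for v in order if isinstance(v, tuple) and v[0] == "S"]


def dating_to_tsv(order: List[str]) -> str:
    lines = ["rank\tspecies_node"]
    lines += [f"{i}\t{s}" for i, s in enumerate(order)]
    return "\n".join(lines) + "\n"
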