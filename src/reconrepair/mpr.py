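"""Maximum-parsimony DTL reconciliation for undated trees.

The dynamic program fills, for every gene node g and species node s, the
minimum cost ``c(g, s)`` of reconciling the gene subtree rooted at g with g
mapped exactly to s.  Three auxiliaries make each cell O(1) amortized:

* ``inn(g, s)``  — best cost of placing g at some ``s' <= s``, charging one
  loss per edge walked down from s to s';
* ``best(g, s)`` — best cost of placing g anywhere in the subtree of s,
  with no loss surcharge (used for the transferred child, whose losses are
  charged from the landing site, which coincides with its own mapping);
* ``out(g, s)``  — best cost of placing g at a species node incomparable
  to s (the transfer target pool).

For internal g with children g1, g2 and species node s:

* speciation (s internal, children x, y):
  ``min(inn(g1,x)+inn(g2,y), inn(g1,y)+inn(g2,x))``
* duplication: ``C_dup + inn(g1,s) + inn(g2,s)``
* transfer: ``C_transfer + min(inn(g1,s)+out(g2,s), inn(g2,s)+out(g1,s))``

``inn``/``best`` propagate by post-order over S, ``out`` by pre-order via
``out(g,x) = min(out(g, pa(x)), best(g, sibling(x)))``.  The optimum is
``min_s c(rt(G), s)``, which lower-bounds the cost of every valid scenario
(temporally feasible or not).

Traceback yields a scenario whose event-based cost (loss counting included)
equals the table value exactly; the landing site of a traced transfer is the
transferred child's own mapping node, the unique zero-landing-loss choice.
Co-optimal reconciliations are enumerated depth-first over the traceback
choice points in a fixed, documented order, so enumeration is deterministic.

All arithmetic is exact (``fractions.Fraction``), so ties are ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterator, List, Optional, Tuple

from .scenario import (
    DUPLICATION,
    SPECIATION,
    TRANSFER,
    DTLScenario,
    ProblemInstance,
)

__all__ = ["DPTables", "compute_tables", "traceback", "enumerate_mprs"]

Cell = Dict[Tuple[str, str], Fraction]


@dataclass
class DPTables:
    """Filled DP tables for one problem instance."""

    inst: ProblemInstance
    c: Cell
    inn: Cell
    best: Cell
    out: Cell
    unreachable: Fraction
    optimal_cost: Fraction

    def is_reachable(self, value: Fraction) -> bool:
        return value < self.unreachable


def compute_tables(inst: ProblemInstance) -> DPTables:
    """Fill the reconciliation tables; runs in O(|G| * |S|)."""
    S, G, L = inst.host, inst.parasite, inst.leaf_map
    cd, ct, cl = inst.costs.duplication, inst.costs.transfer, inst.costs.loss

    # Strictly larger than any achievable scenario cost: every internal gene
    # node contributes at most max(cd, ct) plus losses bounded by two full
    # traversals of S.  Finite so that min() needs no special cases.
    n_int = len(G.internal_nodes)
    unreachable = (cd + ct + cl * 2 * len(S.nodes)) * n_int + 1

    c: Cell = {}
    inn: Cell = {}
    best: Cell = {}
    out: Cell = {}

    s_post = S.postorder()
    s_pre = S.preorder()

    def fill_aux(g: str) -> None:
        for s in s_post:
            v = c[(g, s)]
            b = v
            if not S.is_leaf(s):
                x, y = S.children_of(s)
                v = min(v, cl + inn[(g, x)], cl + inn[(g, y)])
                b = min(b, best[(g, x)], best[(g, y)])
            inn[(g, s)] = min(v, unreachable)
            best[(g, s)] = min(b, unreachable)
        out[(g, S.root)] = unreachable
        for s in s_pre:
            if s == S.root:
                continue
            sib = S.sibling_of(s)
            out[(g, s)] = min(out[(g, S.parent_of(s))], best[(g, sib)])

    for g in G.postorder():
        if G.is_leaf(g):
            target = L[g]
            for s in s_post:
                c[(g, s)] = Fraction(0) if s == target else unreachable
        else:
            g1, g2 = G.children_of(g)
            for s in s_post:
                value = unreachable
                if not S.is_leaf(s):
                    x, y = S.children_of(s)
                    value = min(
                        value,
                        inn[(g1, x)] + inn[(g2, y)],
                        inn[(g1, y)] + inn[(g2, x)],
                    )
                value = min(value, cd + inn[(g1, s)] + inn[(g2, s)])
                value = min(
                    value,
                    ct + inn[(g1, s)] + out[(g2, s)],
                    ct + inn[(g2, s)] + out[(g1, s)],
                )
                c[(g, s)] = min(value, unreachable)
        fill_aux(g)

    root = G.root
    optimal = min(c[(root, s)] for s in s_post)
    assert optimal < unreachable, "total leaf map must admit a reconciliation"
    return DPTables(inst, c, inn, best, out, unreachable, optimal)


# ---------------------------------------------------------------------------
# Traceback / enumeration.
#
# Each expander yields partial scenarios (fragments) for a gene subtree, in a
# fixed deterministic order; the cartesian products below therefore give a
# fixed global enumeration order.  Fragments produced for a fixed (g, s) pair
# are structurally distinct by construction (different event label, child
# placement, or transfer direction), so no de-duplication is needed, but
# enumerate_mprs keeps a seen-set as a cheap safety net.
# ---------------------------------------------------------------------------


def _merge(
    g: str,
    s: str,
    event: Optional[str],
    fragments: Tuple[DTLScenario, ...],
    transfer_edge: Optional[Tuple[str, str]] = None,
    landing: Optional[str] = None,
) -> DTLScenario:
    mapping: Dict[str, str] = {g: s}
    events: Dict[str, str] = {}
    edges = set()
    lands: Dict[str, str] = {}
    for frag in fragments:
        mapping.update(frag.mapping)
        events.update(frag.events)
        edges |= frag.transfer_edges
        lands.update(frag.landing)
    if event is not None:
        events[g] = event
    if transfer_edge is not None:
        edges.add(transfer_edge)
    if landing is not None:
        lands[g] = landing
    return DTLScenario(mapping, events, edges, lands)


class _Expander:
    def __init__(self, tables: DPTables):
        self.t = tables
        self.S = tables.inst.host
        self.G = tables.inst.parasite
        self.costs = tables.inst.costs

    def exact(self, g: str, s: str) -> Iterator[DTLScenario]:
        """Scenarios for G(g) with g mapped exactly to s, cost c(g, s)."""
        t, S, G = self.t, self.S, self.G
        target = t.c[(g, s)]
        if not t.is_reachable(target):
            return
        if G.is_leaf(g):
            yield DTLScenario({g: s}, {}, set(), {})
            return
        g1, g2 = G.children_of(g)
        # event priority: speciation < duplication < transfer
        if not S.is_leaf(s):
            x, y = S.children_of(s)
            for a, b in ((x, y), (y, x)):
                if t.inn[(g1, a)] + t.inn[(g2, b)] == target:
                    for f1 in self.within(g1, a):
                        for f2 in self.within(g2, b):
                            yield _merge(g, s, SPECIATION, (f1, f2))
        if self.costs.duplication + t.inn[(g1, s)] + t.inn[(g2, s)] == target:
            for f1 in self.within(g1, s):
                for f2 in self.within(g2, s):
                    yield _merge(g, s, DUPLICATION, (f1, f2))
        for stay, move in ((g1, g2), (g2, g1)):
            if self.costs.transfer + t.inn[(stay, s)] + t.out[(move, s)] == target:
                for fs in self.within(stay, s):
                    for fm in self.outside(move, s):
                        site = fm.mapping[move]
                        yield _merge(
                            g, s, TRANSFER, (fs, fm),
                            transfer_edge=(g, move), landing=site,
                        )

    def within(self, g: str, s: str) -> Iterator[DTLScenario]:
        """Placements s' <= s realising inn(g, s): losses charged per edge."""
        t, S = self.t, self.S
        target = t.inn[(g, s)]
        if not t.is_reachable(target):
            return
        if t.c[(g, s)] == target:
            yield from self.exact(g, s)
        if not S.is_leaf(s):
            for child in S.children_of(s):
                if self.costs.loss + t.inn[(g, child)] == target:
                    yield from self.within(g, child)

    def subtree(self, g: str, s: str) -> Iterator[DTLScenario]:
        """Placements s' <= s realising best(g, s) (no loss surcharge)."""
        t, S = self.t, self.S
        target = t.best[(g, s)]
        if not t.is_reachable(target):
            return
        if t.c[(g, s)] == target:
            yield from self.exact(g, s)
        if not S.is_leaf(s):
            for child in S.children_of(s):
                if t.best[(g, child)] == target:
                    yield from self.subtree(g, child)

    def outside(self, g: str, s: str) -> Iterator[DTLScenario]:
        """Placements incomparable to s realising out(g, s)."""
        t, S = self.t, self.S
        target = t.out[(g, s)]
        if not t.is_reachable(target):
            return
        sib = S.sibling_of(s)
        if sib is not None and t.best[(g, sib)] == target:
            yield from self.subtree(g, sib)
        parent = S.parent_of(s)
        if parent is not None and t.out[(g, parent)] == target:
            yield from self.outside(g, parent)


def _enumerate(tables: DPTables) -> Iterator[DTLScenario]:
    exp = _Expander(tables)
    root = tables.inst.parasite.root
    for s in tables.inst.host.postorder():
        if tables.c[(root, s)] == tables.optimal_cost:
            yield from exp.exact(root, s)


def enumerate_mprs(
    tables: DPTables, inst: Optional[ProblemInstance] = None, limit: int = 10
) -> List[DTLScenario]:
    """First ``limit`` co-optimal reconciliations in the deterministic order.

    Returns ``min(limit, number of co-optima)`` pairwise-distinct valid
    scenarios, each with cost equal to the table optimum.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    out: List[DTLScenario] = []
    seen = set()
    for sc in _enumerate(tables):
        key = sc.canonical_key()
        if key in seen:  # pragma: no cover - expansions are distinct by design
            continue
        seen.add(key)
        out.append(sc)
        if len(out) >= limit:
            break
    return out


def traceback(
    tables: DPTables, inst: Optional[ProblemInstance] = None
) -> DTLScenario:
    """The first reconciliation in the deterministic enumeration order."""
    return enumerate_mprs(tables, inst, limit=1)[0]
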