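"""Iterative repair of temporally infeasible reconciliations.

An undated maximum-parsimony reconciliation may be impossible to date: the
feasibility graph has a cycle.  The repair loop greedily restores
feasibility by "pulling up" gene nodes in the host tree:

* select a gene node on a cycle whose mapping is lowest in the host tree
  (no other cycle-bound gene node maps to a proper descendant of it);
* pull it up one level: a speciation becomes a duplication in place; a
  duplication moves to the parent species node; a transfer moves to the
  parent species node and converts to a duplication if the new mapping
  dominates its landing site (otherwise it stays a transfer);
* rebuild the feasibility graph and repeat until acyclic.

Every intermediate scenario remains valid, the loop terminates (a node
mapped to the host root is never selected, because root-mapped vertices
cannot lie on a cycle), and the cost increase is bounded: at most
``k * h_G`` added duplications and ``k * h_G * h_S`` added losses, where k
is the number of transfers in the input reconciliation and h_G, h_S are
the tree heights.  The final cost can only exceed the maximum-parsimony
lower bound, never undercut it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Tuple

from .feasibility import (
    FeasibilityGraph,
    build_feasibility_graph,
    nodes_on_cycles,
)
from .mpr import compute_tables, enumerate_mprs
from .scenario import (
    DUPLICATION,
    SPECIATION,
    TRANSFER,
    DTLScenario,
    ProblemInstance,
    scenario_cost,
)

logger = logging.getLogger("reconrepair")

__all__ = [
    "RepairStep",
    "RepairTrace",
    "RepairCandidate",
    "RepairBestReport",
    "select_repair_node",
    "pull_up",
    "repair",
    "repair_best",
]


@dataclass(frozen=True)
class RepairStep:
    iteration: int
    gene_node: str
    old_event: str
    old_mapping: str
    new_event: str
    new_mapping: str
    landing_dropped: bool
    cost_after: Fraction


@dataclass
class RepairTrace:
    """Ordered log of pull-up steps plus the a-priori bounds they must obey."""

    steps: List[RepairStep] = field(default_factory=list)
    initial_transfers: int = 0  # k: transfer count of the input scenario
    h_parasite: int = 0
    h_host: int = 0
    initial_cost: Fraction = Fraction(0)
    final_cost: Fraction = Fraction(0)
    added_duplications: int = 0
    added_losses: int = 0

    @property
    def step_cap(self) -> int:
        """Defensive termination cap: |I(G)| * (h_S + 1)."""
        return self._n_internal * (self.h_host + 1)

    _n_internal: int = 0

    @property
    def duplication_bound(self) -> int:
        return self.initial_transfers * self.h_parasite

    @property
    def loss_bound(self) -> int:
        return self.initial_transfers * self.h_parasite * self.h_host

    def to_json(self) -> str:
        return json.dumps(
            {
                "steps": [
                    {
                        "iteration": st.iteration,
                        "gene_node": st.gene_node,
                        "old": {"event": st.old_event, "mapping": st.old_mapping},
                        "new": {"event": st.new_event, "mapping": st.new_mapping},
                        "landing_dropped": st.landing_dropped,
                        "cost_after": float(st.cost_after),
                    }
                    for st in self.steps
                ],
                "initial_transfers": self.initial_transfers,
                "h_parasite": self.h_parasite,
                "h_host": self.h_host,
                "initial_cost": float(self.initial_cost),
                "final_cost": float(self.final_cost),
                "added_duplications": self.added_duplications,
                "added_losses": self.added_losses,
                "duplication_bound": self.duplication_bound,
                "loss_bound": self.loss_bound,
            },
            indent=2,
        )


def select_repair_node(
    inst: ProblemInstance, sc: DTLScenario, fg: FeasibilityGraph
) -> Optional[str]:
    """A lowest-mapped gene node on a cycle, or ``None`` if the graph is acyclic.

    Internal gene nodes are scanned sorted by the host post-order index of
    their mapping (ties broken by parasite post-order index), and the first
    cycle-bound one is returned, so no cycle-bound gene node maps to a
    proper descendant of the selection's mapping.
    """
    cycle_nodes = nodes_on_cycles(fg)
    if not cycle_nodes:
        return None
    S, G = inst.host, inst.parasite
    candidates = sorted(
        cycle_nodes,
        key=lambda g: (S.postorder_index(sc.mapping[g]), G.postorder_index(g)),
    )
    g = candidates[0]
    # A root-mapped gene vertex can never lie on a cycle: nothing outside the
    # root-mapped set points into it, and within the set only gene ancestry
    # edges exist.  A selection violating this indicates a construction bug.
    assert sc.mapping[g] != S.root, "cycle through a root-mapped gene node"
    return g


def _one_level(inst: ProblemInstance, sc: DTLScenario, g: str) -> bool:
    """Apply the single-node pull-up rule to ``g`` in place.

    Speciation: becomes a duplication at the same species node.
    Duplication: moves to the parent species node.
    Transfer: moves to the parent species node; if the new mapping strictly
    dominates the landing site the node becomes a duplication (its transfer
    edge and landing site are dropped), otherwise it stays a transfer.
    Returns True iff the mapping actually moved.
    """
    S = inst.host
    event = sc.events[g]
    if event == SPECIATION:
        sc.events[g] = DUPLICATION
        return False
    parent = S.parent_of(sc.mapping[g])
    sc.mapping[g] = parent
    if event == TRANSFER:
        site = sc.landing[g]
        if S.is_strict_ancestor(parent, site):
            sc.events[g] = DUPLICATION
            sc.transfer_edges.discard((g, sc.transferred_child(g)))
            del sc.landing[g]
    return True


def pull_up(inst: ProblemInstance, sc: DTLScenario, g: str) -> DTLScenario:
    """Remap gene node ``g`` one level up in the host tree; output stays valid.

    The single-node rule (:func:`_one_level`) is applied to ``g``.  When the
    raised mapping overtakes the gene parent's placement, the parent is
    adjusted by the minimal matching moves, so that the result is a valid
    scenario in every configuration, which the single-node rule alone does
    not guarantee:

    * a parent mapped to the same species node (a co-mapped duplication or
      transfer, or a speciation whose child image caught up with it) is
      itself pulled one level at a time until it is no longer below the
      raised child;
    * a parent that transferred ``g`` must keep its landing site above
      ``g``'s image: the site is lifted to the child's new mapping; if that
      makes takeoff and landing comparable the transfer collapses into a
      duplication at the child's mapping.

    Adjusted parents are re-examined against their own parents, so the
    cascade propagates rootward as far as needed (each step only moves
    mappings upward, so it terminates).
    """
    S, G = inst.host, inst.parasite
    if G.is_leaf(g):
        raise ValueError(f"cannot pull up leaf node {g!r}")
    if sc.events[g] != SPECIATION and sc.mapping[g] == S.root:
        raise ValueError(f"cannot pull {g!r} above the host root")

    new = sc.copy()
    moved = _one_level(inst, new, g)
    worklist = [g] if moved else []
    while worklist:
        v = worklist.pop()
        q = G.parent_of(v)
        if q is None:
            continue
        mv = new.mapping[v]
        if (q, v) in new.transfer_edges:
            if not S.is_ancestor_or_equal(new.landing[q], mv):
                new.landing[q] = mv
                if not S.incomparable(new.mapping[q], mv):
                    # landing caught up with the takeoff lineage: the event
                    # is no longer a host switch
                    new.events[q] = DUPLICATION
                    new.transfer_edges.discard((q, v))
                    del new.landing[q]
                    new.mapping[q] = mv
                    worklist.append(q)
        else:
            raised = False
            while S.is_strict_ancestor(mv, new.mapping[q]) or (
                mv == new.mapping[q] and new.events[q] == SPECIATION
            ):
                raised = _one_level(inst, new, q) or raised
            if raised:
                worklist.append(q)
    return new


def repair(
    inst: ProblemInstance, sc: DTLScenario
) -> Tuple[DTLScenario, RepairTrace]:
    """Pull gene nodes up until the scenario is temporally feasible.

    The feasibility graph is rebuilt from scratch after every pull-up.  If
    the input is already feasible it is returned unchanged with an empty
    trace.  Exceeding the termination cap raises (it would contradict the
    termination argument and signals a bug).
    """
    S, G = inst.host, inst.parasite
    initial_report = scenario_cost(inst, sc)
    trace = RepairTrace(
        initial_transfers=initial_report.n_transfers,
        h_parasite=G.height,
        h_host=S.height,
        initial_cost=initial_report.total_cost,
        final_cost=initial_report.total_cost,
        _n_internal=len(G.internal_nodes),
    )
    current = sc
    iteration = 0
    while True:
        fg = build_feasibility_graph(inst, current)
        g = select_repair_node(inst, current, fg)
        if g is None:
            break
        iteration += 1
        if iteration > trace.step_cap:
            raise RuntimeError(
                "repair exceeded its termination cap; this should be impossible"
            )
        old_event, old_mapping = current.events[g], current.mapping[g]
        current = pull_up(inst, current, g)
        report = scenario_cost(inst, current)  # raises if the step broke validity
        step = RepairStep(
            iteration=iteration,
            gene_node=g,
            old_event=old_event,
            old_mapping=old_mapping,
            new_event=current.events[g],
            new_mapping=current.mapping[g],
            landing_dropped=(old_event == TRANSFER
                             and current.events[g] == DUPLICATION),
            cost_after=report.total_cost,
        )
        trace.steps.append(step)
        trace.final_cost = report.total_cost
        logger.info(
            "repair step %d: %s %s@%s -> %s@%s (cost %s)",
            iteration, g, old_event, old_mapping,
            current.events[g], current.mapping[g], float(report.total_cost),
        )
    final_report = scenario_cost(inst, current)
    trace.final_cost = final_report.total_cost
    trace.added_duplications = final_report.n_duplications - initial_report.n_duplications
    trace.added_losses = final_report.total_losses - initial_report.total_losses
    return current, trace


@dataclass(frozen=True)
class RepairCandidate:
    index: int
    pre_repair_cost: Fraction
    post_repair_cost: Fraction
    was_feasible: bool
    n_steps: int


@dataclass(frozen=True)
class RepairBestReport:
    lower_bound: Fraction
    candidates: Tuple[RepairCandidate, ...]
    best_index: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "lower_bound": float(self.lower_bound),
                "best_index": self.best_index,
                "candidates": [
                    {
                        "index": c.index,
                        "pre_repair_cost": float(c.pre_repair_cost),
                        "post_repair_cost": float(c.post_repair_cost),
                        "was_feasible": c.was_feasible,
                        "n_steps": c.n_steps,
                    }
                    for c in self.candidates
                ],
            },
            indent=2,
        )


def repair_best(
    inst: ProblemInstance, n: int = 10
) -> Tuple[DTLScenario, RepairBestReport]:
    """Enumerate up to ``n`` co-optimal reconciliations, repair each, keep the best.

    Ties are broken by enumeration order.  The report records, for every
    candidate, its (shared, optimal) pre-repair cost and its post-repair
    cost, plus the maximum-parsimony lower bound.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tables = compute_tables(inst)
    candidates = enumerate_mprs(tables, inst, limit=n)
    results: List[RepairCandidate] = []
    repaired: List[DTLScenario] = []
    for i, sc in enumerate(candidates):
        fixed, trace = repair(inst, sc)
        repaired.append(fixed)
        results.append(
            RepairCandidate(
                index=i,
                pre_repair_cost=trace.initial_cost,
                post_repair_cost=trace.final_cost,
                was_feasible=(not trace.steps),
                n_steps=len(trace.steps),
            )
        )
    best_index = min(range(len(results)), key=lambda i: results[i].post_repair_cost)
    report = RepairBestReport(
        lower_bound=tables.optimal_cost,
        candidates=tuple(results),
        best_index=best_index,
    )
    return repaired[best_index], report
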