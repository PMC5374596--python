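"""The DTL-scenario data model: events, constraints, losses, and cost.

A DTL-scenario reconciles a parasite (gene) tree G with a host (species)
tree S using four event types: speciation (cost 0), duplication, transfer
(host switch), and loss.  A scenario is the seven-tuple
(leaf map, node map M, speciation/duplication/transfer partition of the
internal gene nodes, transfer-edge set, landing-site map tau), subject to
four validity constraints enforced by :func:`validate_scenario`:

1. M extends the leaf map on parasite leaves.
2. M(g) is never strictly below a child's image, and at least one child's
   image lies in the subtree of M(g).
3. A gene edge is a transfer edge iff its endpoint images are incomparable.
4. Event labels are consistent: a speciation sits at the LCA of incomparable
   child images; a duplication sits at or above the LCA; a node is a transfer
   iff it has an incident transfer edge; a transfer's landing site is
   incomparable to its takeoff mapping and dominates the transferred child.

Losses are inferred per internal gene node from path lengths in S.  Note the
transfer case charges the non-transferred child from M(g) and the transferred
child from the landing site, with no ``-1`` correction terms, unlike the
speciation case; the counting rule is asymmetric by definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple, Union

from .trees import RootedBinaryTree

__all__ = [
    "SPECIATION",
    "DUPLICATION",
    "TRANSFER",
    "EventCosts",
    "ProblemInstance",
    "DTLScenario",
    "Violation",
    "ReconciliationReport",
    "InvalidScenarioError",
    "validate_scenario",
    "losses_at",
    "scenario_cost",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
TRANSFER = "transfer"
EVENT_TYPES = (SPECIATION, DUPLICATION, TRANSFER)

CostLike = Union[int, float, str, Fraction]


def _as_fraction(value: CostLike) -> Fraction:
    # str(float) round-trips decimal literals (0.1 -> Fraction(1, 10)),
    # giving exact arithmetic for every cost a user can type.
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class EventCosts:
    """Positive costs for duplication, transfer, and loss; speciation is free."""

    duplication: Fraction
    transfer: Fraction
    loss: Fraction

    def __init__(self, duplication: CostLike, transfer: CostLike, loss: CostLike):
        object.__setattr__(self, "duplication", _as_fraction(duplication))
        object.__setattr__(self, "transfer", _as_fraction(transfer))
        object.__setattr__(self, "loss", _as_fraction(loss))
        for name in ("duplication", "transfer", "loss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} cost must be strictly positive")


@dataclass(frozen=True)
class ProblemInstance:
    """A reconciliation problem: host tree, parasite tree, leaf map, costs."""

    host: RootedBinaryTree
    parasite: RootedBinaryTree
    leaf_map: Mapping[str, str]
    costs: EventCosts

    def __post_init__(self) -> None:
        if not self.host.internal_nodes or not self.parasite.internal_nodes:
            raise ValueError(
                "reconciliation requires at least one internal node in each tree"
            )
        from .trees import validate_leaf_mapping

        object.__setattr__(
            self,
            "leaf_map",
            validate_leaf_mapping(self.leaf_map, self.parasite, self.host),
        )


@dataclass
class DTLScenario:
    """A (possibly temporally infeasible) reconciliation of G into S.

    ``mapping`` is total over V(G); ``events`` is total over the internal
    nodes of G; ``transfer_edges`` holds (parent, child) gene edges whose
    endpoint images are incomparable; ``landing`` gives each transfer node's
    recipient species node.
    """

    mapping: Dict[str, str]
    events: Dict[str, str]
    transfer_edges: Set[Tuple[str, str]] = field(default_factory=set)
    landing: Dict[str, str] = field(default_factory=dict)

    def copy(self) -> "DTLScenario":
        return DTLScenario(
            dict(self.mapping),
            dict(self.events),
            set(self.transfer_edges),
            dict(self.landing),
        )

    @property
    def speciations(self) -> FrozenSet[str]:
        return frozenset(g for g, e in self.events.items() if e == SPECIATION)

    @property
    def duplications(self) -> FrozenSet[str]:
        return frozenset(g for g, e in self.events.items() if e == DUPLICATION)

    @property
    def transfers(self) -> FrozenSet[str]:
        return frozenset(g for g, e in self.events.items() if e == TRANSFER)

    def transferred_child(self, g: str) -> Optional[str]:
        """The child of ``g`` reached through its transfer edge, if any."""
        for parent, child in self.transfer_edges:
            if parent == g:
                return child
        return None

    def canonical_key(self) -> Tuple:
        """Hashable identity used to de-duplicate enumerated scenarios."""
        return (
            tuple(sorted(self.mapping.items())),
            tuple(sorted(self.events.items())),
            tuple(sorted(self.transfer_edges)),
            tuple(sorted(self.landing.items())),
        )

    def to_dict(self) -> Dict:
        return {
            "mapping": dict(sorted(self.mapping.items())),
            "events": dict(sorted(self.events.items())),
            "transfer_edges": sorted(list(e) for e in self.transfer_edges),
            "landing": dict(sorted(self.landing.items())),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "DTLScenario":
        return cls(
            mapping=dict(data["mapping"]),
            events=dict(data["events"]),
            transfer_edges={tuple(e) for e in data.get("transfer_edges", [])},
            landing=dict(data.get("landing", {})),
        )


@dataclass(frozen=True)
class Violation:
    """One failed validity constraint, attributed to a gene node."""

    gene_node: str
    constraint: str
    message: str

    def __str__(self) -> str:
        return f"[{self.constraint}] at {self.gene_node}: {self.message}"


class InvalidScenarioError(ValueError):
    def __init__(self, violations: List[Violation]):
        self.violations = violations
        super().__init__(
            "invalid DTL-scenario: " + "; ".join(str(v) for v in violations)
        )


def validate_scenario(inst: ProblemInstance, sc: DTLScenario) -> List[Violation]:
    """Check a scenario against the validity constraints.

    All violations are collected (not fail-fast), in fixed order: structural
    totality checks first, then Constraints 1, 2, 3, 4.1-4.4.  An empty
    return value means the scenario is valid.
    """
    S, G = inst.host, inst.parasite
    out: List[Violation] = []

    internal = set(G.internal_nodes)
    for g in G.nodes:
        if g not in sc.mapping:
            out.append(Violation(g, "structure", "no mapping for gene node"))
        elif sc.mapping[g] not in S:
            out.append(
                Violation(g, "structure", f"mapped to unknown species node "
                                          f"{sc.mapping[g]!r}")
            )
    for g in internal:
        ev = sc.events.get(g)
        if ev not in EVENT_TYPES:
            out.append(Violation(g, "structure", f"missing or bad event {ev!r}"))
    for g in sc.events:
        if g not in internal:
            out.append(Violation(g, "structure", "event assigned to a non-internal node"))
    for parent, child in sc.transfer_edges:
        if parent not in internal or G.parent_of(child) != parent:
            out.append(Violation(parent, "structure",
                                 f"({parent}, {child}) is not a gene-tree edge"))
    transfer_nodes = {g for g, e in sc.events.items() if e == TRANSFER}
    if set(sc.landing) != transfer_nodes:
        extra = set(sc.landing) - transfer_nodes
        missing = transfer_nodes - set(sc.landing)
        for g in sorted(extra):
            out.append(Violation(g, "structure", "landing site on a non-transfer node"))
        for g in sorted(missing):
            out.append(Violation(g, "structure", "transfer node without landing site"))
    if out:
        return out  # mappings incomplete; constraint checks would KeyError

    # Constraint 1: M extends the leaf map
    for g in G.leaves:
        if sc.mapping[g] != inst.leaf_map[g]:
            out.append(Violation(
                g, "Constraint 1",
                f"M({g})={sc.mapping[g]} != leaf map image {inst.leaf_map[g]}"))

    for g in G.internal_nodes:
        gl, gr = G.children_of(g)
        mg, ml, mr = sc.mapping[g], sc.mapping[gl], sc.mapping[gr]

        # Constraint 2
        if S.is_strict_ancestor(ml, mg) or S.is_strict_ancestor(mr, mg):
            out.append(Violation(g, "Constraint 2",
                                 "M(g) lies strictly below a child image"))
        if not (S.is_ancestor_or_equal(mg, ml) or S.is_ancestor_or_equal(mg, mr)):
            out.append(Violation(g, "Constraint 2",
                                 "no child image is a descendant of M(g)"))

        # Constraint 3: transfer edges <=> incomparable endpoint images
        for child, mc in ((gl, ml), (gr, mr)):
            on_edge = (g, child) in sc.transfer_edges
            incomp = S.incomparable(mg, mc)
            if on_edge and not incomp:
                out.append(Violation(g, "Constraint 3",
                                     f"transfer edge ({g},{child}) but images comparable"))
            if incomp and not on_edge:
                out.append(Violation(g, "Constraint 3",
                                     f"images of ({g},{child}) incomparable but edge "
                                     f"not marked as transfer"))

        ev = sc.events[g]
        incident = [(g, c) in sc.transfer_edges for c in (gl, gr)]
        if ev == SPECIATION:
            # Constraint 4.1
            if mg != S.lca(ml, mr) or not S.incomparable(ml, mr):
                out.append(Violation(g, "Constraint 4.1",
                                     "speciation must sit at the LCA of "
                                     "incomparable child images"))
        elif ev == DUPLICATION:
            # Constraint 4.2
            if not S.is_ancestor_or_equal(mg, S.lca(ml, mr)):
                out.append(Violation(g, "Constraint 4.2",
                                     "duplication must sit at or above the LCA "
                                     "of the child images"))
        # Constraint 4.3: transfer <=> an incident transfer edge
        if (ev == TRANSFER) != any(incident):
            out.append(Violation(g, "Constraint 4.3",
                                 "transfer label and incident transfer edges disagree"))
        if sum(incident) > 1:
            out.append(Violation(g, "Constraint 4.3",
                                 "more than one incident transfer edge"))
        # Constraint 4.4: landing site placement
        if ev == TRANSFER and sum(incident) == 1 and g in sc.landing:
            site = sc.landing[g]
            if site not in S:
                out.append(Violation(g, "Constraint 4.4",
                                     f"unknown landing site {site!r}"))
            else:
                moved = gl if incident[0] else gr
                if not S.incomparable(mg, site):
                    out.append(Violation(g, "Constraint 4.4",
                                         "landing site comparable to M(g)"))
                if not S.is_ancestor_or_equal(site, sc.mapping[moved]):
                    out.append(Violation(g, "Constraint 4.4",
                                         "transferred child not below the landing site"))
    return out


def losses_at(inst: ProblemInstance, sc: DTLScenario, g: str) -> int:
    """Number of loss events charged to internal gene node ``g``.

    Speciation: ``(d(M(g),M(gl))-1) + (d(M(g),M(gr))-1)``.
    Duplication: ``d(M(g),M(gl)) + d(M(g),M(gr))``.
    Transfer with transferred child g': ``d(M(g),M(other)) + d(tau(g),M(g'))``.
    """
    G, S = inst.parasite, inst.host
    if G.is_leaf(g):
        raise ValueError(f"losses are defined only at internal gene nodes, got {g!r}")
    gl, gr = G.children_of(g)
    mg, ml, mr = sc.mapping[g], sc.mapping[gl], sc.mapping[gr]
    ev = sc.events[g]
    if ev == SPECIATION:
        return (S.path_length(mg, ml) - 1) + (S.path_length(mg, mr) - 1)
    if ev == DUPLICATION:
        return S.path_length(mg, ml) + S.path_length(mg, mr)
    moved = sc.transferred_child(g)
    stay = gr if moved == gl else gl
    return S.path_length(mg, sc.mapping[stay]) + S.path_length(
        sc.landing[g], sc.mapping[moved]
    )


@dataclass(frozen=True)
class ReconciliationReport:
    """Event counts, per-node losses, and total weighted cost of a scenario."""

    total_cost: Fraction
    n_speciations: int
    n_duplications: int
    n_transfers: int
    total_losses: int
    losses_by_node: Mapping[str, int]

    def to_json(self, sc: Optional[DTLScenario] = None) -> str:
        payload = {
            "total_cost": float(self.total_cost),
            "speciations": self.n_speciations,
            "duplications": self.n_duplications,
            "transfers": self.n_transfers,
            "losses": self.total_losses,
            "losses_by_node": dict(sorted(self.losses_by_node.items())),
        }
        if sc is not None:
            payload["scenario"] = sc.to_dict()
        return json.dumps(payload, indent=2)

    def to_tsv(self, sc: DTLScenario) -> str:
        """Flat events table: gene node, event, M(g), landing site, losses."""
        lines = ["gene_node\tevent\tmapping\tlanding\tlosses"]
        for g in sorted(sc.events):
            lines.append("\t".join([
                g,
                sc.events[g],
                sc.mapping[g],
                sc.landing.get(g, "-"),
                str(self.losses_by_node[g]),
            ]))
        return "\n".join(lines) + "\n"


def scenario_cost(inst: ProblemInstance, sc: DTLScenario) -> ReconciliationReport:
    """Score a valid scenario: ``C_dup*|D| + C_transfer*|T| + C_loss*losses``."""
    violations = validate_scenario(inst, sc)
    if violations:
        raise InvalidScenarioError(violations)
    losses = {g: losses_at(inst, sc, g) for g in inst.parasite.internal_nodes}
    n_dup = len(sc.duplications)
    n_tr = len(sc.transfers)
    total_losses = sum(losses.values())
    cost = (
        inst.costs.duplication * n_dup
        + inst.costs.transfer * n_tr
        + inst.costs.loss * total_losses
    )
    return ReconciliationReport(
        total_cost=cost,
        n_speciations=len(sc.speciations),
        n_duplications=n_dup,
        n_transfers=n_tr,
        total_losses=total_losses,
        losses_by_node=losses,
    )
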