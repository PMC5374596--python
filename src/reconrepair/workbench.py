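"""Synthetic instance generation and brute-force test oracles.

The simulator grows a random host tree and evolves a parasite tree down it
with per-node probabilities of duplication, host switch, and loss
(cospeciation takes the remaining mass).  It is a seeded, deterministic
codivergence model: parasite lineages track host lineages, switch to
incomparable hosts, and go extinct on a host branch with the loss
probability.  Its purpose is to produce transfer-rich
instances whose maximum-parsimony reconciliations are sometimes temporally
infeasible; it makes no claim of biological realism.

The two oracles are intentionally naive and independent of the production
code paths they cross-check:

* :func:`brute_force_mpr` enumerates every valid scenario (all node maps,
  event labels, and landing sites) and scores each by the event/loss
  definitions, returning the exact optimum and all optimal scenarios;
* :func:`brute_force_feasibility` searches all ancestry-consistent total
  orders of the internal host nodes and, for each, greedily schedules
  event times (speciations pinned to their host node's date, duplications
  strictly inside the host edge above their mapping, transfers at a common
  time strictly inside both the takeoff and the landing edge, parent
  events strictly before child events).

Both guard their input size with hard errors; they exist for testing, not
for analysis of real data.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .scenario import (
    DUPLICATION,
    SPECIATION,
    TRANSFER,
    DTLScenario,
    EventCosts,
    ProblemInstance,
    validate_scenario,
)
from .trees import RootedBinaryTree

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "generate_instance",
    "brute_force_mpr",
    "brute_force_feasibility",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the coevolution simulator.

    ``p_duplication``, ``p_switch``: per-visit probabilities of a parasite
    duplicating or switching hosts at an internal host node (cospeciation
    takes the rest).  ``p_loss``: probability that a parasite lineage dies
    on a host branch it would otherwise follow.  Defaults produce the
    switch-rich regime in which infeasible reconciliations actually occur.
    """

    host_leaves: int = 8
    p_duplication: float = 0.05
    p_switch: float = 0.3
    p_loss: float = 0.1
    seed: int = 0
    costs: EventCosts = field(default_factory=lambda: EventCosts(2, 3, 1))
    max_parasite_leaves: int = 64
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.host_leaves < 2:
            raise ValueError("host_leaves must be >= 2")
        for name in ("p_duplication", "p_switch", "p_loss"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_duplication + self.p_switch >= 1.0:
            raise ValueError("p_duplication + p_switch must be < 1")


def _random_host_tree(rng: random.Random, n_leaves: int) -> RootedBinaryTree:
    # uniform random joins (coalescent-style) over leaf lineages
    lineages: List[str] = [f"H{i}" for i in range(n_leaves)]
    children: Dict[str, Tuple[str, str]] = {}
    counter = 0
    while len(lineages) > 1:
        i, j = rng.sample(range(len(lineages)), 2)
        a, b = lineages[i], lineages[j]
        name = f"h{counter}"
        counter += 1
        children[name] = (a, b)
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(name)
    return RootedBinaryTree(lineages[0], children)


# nested parasite tree representation during simulation
_SimNode = Union[str, Tuple["_SimNode", "_SimNode"]]


def generate_instance(
    cfg: SimulationConfig,
) -> Tuple[ProblemInstance, List[Tuple[str, str]]]:
    """Simulate one host/parasite pair; returns the instance and event history.

    Deterministic: identical configs (including the seed) yield identical
    instances.  Regenerates (bounded retries) when every parasite lineage
    dies or the parasite tree exceeds the size cap.
    """
    rng = random.Random(cfg.seed)
    for _attempt in range(cfg.max_retries):
        host = _random_host_tree(rng, cfg.host_leaves)
        incomparable_pool: Dict[str, List[str]] = {
            v: [u for u in host.nodes if host.incomparable(u, v)]
            for v in host.nodes
        }
        history: List[Tuple[str, str]] = []
        leaf_map: Dict[str, str] = {}
        leaf_counter = [0]
        overflow = [False]
        depth_cap = 8 * host.height + 40

        def new_leaf(host_leaf: str) -> str:
            name = f"P{leaf_counter[0]}"
            leaf_counter[0] += 1
            if leaf_counter[0] > cfg.max_parasite_leaves:
                overflow[0] = True
            leaf_map[name] = host_leaf
            return name

        def follow(host_child: str, depth: int) -> Optional[_SimNode]:
            # traversal of a host branch: the lineage may die on the way
            if rng.random() < cfg.p_loss:
                history.append(("loss", host_child))
                return None
            return evolve(host_child, depth)

        def evolve(host_node: str, depth: int) -> Optional[_SimNode]:
            if overflow[0]:
                return None
            if host.is_leaf(host_node):
                return new_leaf(host_node)
            if depth > depth_cap:
                history.append(("loss", host_node))
                return None
            u = rng.random()
            if u < cfg.p_duplication:
                history.append(("duplication", host_node))
                left = evolve(host_node, depth + 1)
                right = evolve(host_node, depth + 1)
            elif u < cfg.p_duplication + cfg.p_switch and incomparable_pool[host_node]:
                recipient = rng.choice(incomparable_pool[host_node])
                history.append(("host_switch", host_node))
                left = evolve(host_node, depth + 1)
                right = evolve(recipient, depth + 1)
            else:
                history.append(("cospeciation", host_node))
                hl, hr = host.children_of(host_node)
                left = follow(hl, depth + 1)
                right = follow(hr, depth + 1)
            if left is None:
                return right
            if right is None:
                return left
            return (left, right)

        shape = evolve(host.root, 0)
        if overflow[0] or shape is None or isinstance(shape, str):
            continue  # extinct or degenerate or oversized: try again

        # name internal parasite nodes deterministically, pre-order
        children: Dict[str, Tuple[str, str]] = {}
        counter = [0]

        def build_pre(node: _SimNode) -> str:
            if isinstance(node, str):
                return node
            name = f"p{counter[0]}"
            counter[0] += 1
            children[name] = (build_pre(node[0]), build_pre(node[1]))
            return name

        root = build_pre(shape)
        parasite = RootedBinaryTree(root, children)
        used_leaves = set(parasite.leaves)
        inst = ProblemInstance(
            host=host,
            parasite=parasite,
            leaf_map={p: h for p, h in leaf_map.items() if p in used_leaves},
            costs=cfg.costs,
        )
        return inst, history
    raise SimulationError(
        "simulation retry budget exhausted (all parasite lineages kept dying "
        "or the tree kept exceeding the size cap); lower p_loss or p_switch"
    )


# ---------------------------------------------------------------------------
# Oracle 1: exhaustive maximum-parsimony reconciliation.
# ---------------------------------------------------------------------------


def brute_force_mpr(
    inst: ProblemInstance, max_leaves: int = 5
) -> Tuple[object, List[DTLScenario]]:
    """Exact optimum and the complete set of optimal scenarios, by enumeration.

    Enumerates every node map satisfying the placement constraint, derives
    the transfer edges (forced by incomparability), and takes, per internal
    gene node, every admissible event label and landing site.  Because the
    cost decomposes over internal gene nodes for a fixed node map, per-node
    minimisation inside each map is exact.  Guarded to tiny inputs.
    """
    S, G = inst.host, inst.parasite
    if len(S.leaves) > max_leaves or len(G.leaves) > max_leaves:
        raise ValueError(
            f"brute_force_mpr is guarded to <= {max_leaves} leaves per tree"
        )
    cd, ct, cl = inst.costs.duplication, inst.costs.transfer, inst.costs.loss

    internal = list(G.internal_nodes)  # post-order: children before parents
    species = list(S.nodes)

    best_cost = None
    best: List[DTLScenario] = []

    mapping: Dict[str, str] = dict(inst.leaf_map)

    def node_options(g: str) -> List[Tuple[str, Optional[str], object]]:
        """Admissible (event, landing, cost) triples for g under `mapping`."""
        gl, gr = G.children_of(g)
        mg, ml, mr = mapping[g], mapping[gl], mapping[gr]
        incomparable = [S.incomparable(mg, m) for m in (ml, mr)]
        if sum(incomparable) > 1:
            return []
        options: List[Tuple[str, Optional[str], object]] = []
        if any(incomparable):
            moved_map = ml if incomparable[0] else mr
            stay_map = mr if incomparable[0] else ml
            for site in species:
                if S.incomparable(mg, site) and S.is_ancestor_or_equal(site, moved_map):
                    losses = S.path_length(mg, stay_map) + S.path_length(site, moved_map)
                    options.append((TRANSFER, site, ct + cl * losses))
        else:
            lca = S.lca(ml, mr)
            if mg == lca and S.incomparable(ml, mr):
                losses = (S.path_length(mg, ml) - 1) + (S.path_length(mg, mr) - 1)
                options.append((SPECIATION, None, cl * losses))
            if S.is_ancestor_or_equal(mg, lca):
                losses = S.path_length(mg, ml) + S.path_length(mg, mr)
                options.append((DUPLICATION, None, cd + cl * losses))
        return options

    def placement_ok(g: str) -> bool:
        gl, gr = G.children_of(g)
        mg, ml, mr = mapping[g], mapping[gl], mapping[gr]
        if S.is_strict_ancestor(ml, mg) or S.is_strict_ancestor(mr, mg):
            return False
        return S.is_ancestor_or_equal(mg, ml) or S.is_ancestor_or_equal(mg, mr)

    def assemble(choices: Dict[str, Tuple[str, Optional[str], object]]) -> DTLScenario:
        events = {g: c[0] for g, c in choices.items()}
        edges: Set[Tuple[str, str]] = set()
        landing: Dict[str, str] = {}
        for g, (ev, site, _) in choices.items():
            if ev == TRANSFER:
                gl, gr = G.children_of(g)
                moved = gl if S.incomparable(mapping[g], mapping[gl]) else gr
                edges.add((g, moved))
                landing[g] = site
        return DTLScenario(dict(mapping), events, edges, landing)

    def recurse(i: int) -> None:
        nonlocal best_cost, best
        if i == len(internal):
            per_node = {g: node_options(g) for g in internal}
            if any(not opts for opts in per_node.values()):
                return
            total = sum(min(c for _, _, c in per_node[g]) for g in internal)
            nonlocal_best = best_cost
            if nonlocal_best is not None and total > nonlocal_best:
                return
            argmins = {
                g: [o for o in per_node[g] if o[2] == min(c for _, _, c in per_node[g])]
                for g in internal
            }
            scenarios = []
            for combo in itertools.product(*(argmins[g] for g in internal)):
                choices = dict(zip(internal, combo))
                sc = assemble(choices)
                assert not validate_scenario(inst, sc), "oracle built invalid scenario"
                scenarios.append(sc)
            if best_cost is None or total < best_cost:
                best_cost = total
                best = scenarios
            elif total == best_cost:
                best.extend(scenarios)
            return
        g = internal[i]
        for s in species:
            mapping[g] = s
            if placement_ok(g):
                recurse(i + 1)
        del mapping[g]

    recurse(0)
    assert best_cost is not None, "total leaf map always admits a reconciliation"
    # distinct by construction, but keep the contract explicit
    unique = {}
    for sc in best:
        unique.setdefault(sc.canonical_key(), sc)
    return best_cost, list(unique.values())


# ---------------------------------------------------------------------------
# Oracle 2: temporal feasibility by exhaustive search over datings.
# ---------------------------------------------------------------------------


def brute_force_feasibility(inst: ProblemInstance, sc: DTLScenario) -> bool:
    """Feasibility by trying every ancestry-consistent host dating.

    For each total order of the internal host nodes, events are scheduled
    greedily at their earliest admissible times; the scenario is feasible
    iff some order admits a full schedule.  Times are lexicographic
    ``(rank, epsilon-count)`` pairs so that "strictly inside an edge" and
    "strictly after the parent event" are exact.  Guarded to at most 8
    internal nodes across both trees.
    """
    S, G = inst.host, inst.parasite
    if len(S.internal_nodes) + len(G.internal_nodes) > 8:
        raise ValueError("brute_force_feasibility is guarded to <= 8 internal nodes")
    if validate_scenario(inst, sc):
        raise ValueError("scenario must be valid")

    internal_s = list(S.internal_nodes)

    def edge_interval(rank: Dict[str, float], s: str) -> Tuple[float, float]:
        """Open time interval of the host edge ending at s."""
        parent = S.parent_of(s)
        lo = rank[parent] if parent is not None else -math.inf
        hi = rank[s] if not S.is_leaf(s) else math.inf
        return lo, hi

    def schedule_ok(order: Sequence[str]) -> bool:
        rank: Dict[str, float] = {s: i for i, s in enumerate(order)}
        # ancestry consistency of the dating itself
        for s in internal_s:
            parent = S.parent_of(s)
            if parent is not None and rank[parent] > rank[s]:
                return False
        times: Dict[str, Tuple[float, int]] = {}
        for g in G.preorder():
            if G.is_leaf(g):
                continue
            parent = G.parent_of(g)
            after = times[parent] if parent is not None else (-math.inf, 0)
            ev = sc.events[g]
            mg = sc.mapping[g]
            if ev == SPECIATION:
                t = (float(rank[mg]), 0)
                if not t > after:
                    return False
            else:
                if ev == DUPLICATION:
                    lo, hi = edge_interval(rank, mg)
                else:  # transfer: common time inside takeoff and landing edges
                    lo1, hi1 = edge_interval(rank, mg)
                    lo2, hi2 = edge_interval(rank, sc.landing[g])
                    lo, hi = max(lo1, lo2), min(hi1, hi2)
                t = max((lo, 1), (after[0], after[1] + 1))
                if not t[0] < hi:
                    return False
            times[g] = t
        return True

    return any(schedule_ok(order) for order in itertools.permutations(internal_s))
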