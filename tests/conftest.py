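"""Shared fixtures: small hand-built instances used across the suite."""

import pytest

from reconrepair import (
    DTLScenario,
    EventCosts,
    ProblemInstance,
    parse_newick,
)


def make_instance(host_nwk, parasite_nwk, leaf_map, costs=(2, 3, 1)):
    return ProblemInstance(
        host=parse_newick(host_nwk),
        parasite=parse_newick(parasite_nwk),
        leaf_map=leaf_map,
        costs=EventCosts(*costs),
    )


@pytest.fixture
def congruent_pair():
    """Perfectly congruent 2-leaf trees: one cospeciation, cost 0."""
    return make_instance("(A,B)r;", "(p,q)g;", {"p": "A", "q": "B"})


@pytest.fixture
def three_leaf_instance():
    """Host ((A,B)x,C)r, parasite ((p,q)w,v)g, map p->A q->C v->B.

    Under unit costs the optimum is one speciation plus one transfer
    (cost 1); with transfer cost above 4 it is one speciation, one
    duplication, and three losses (cost 4).
    """

    def build(costs):
        return make_instance(
            "((A,B)x,C)r;", "((p,q)w,v)g;",
            {"p": "A", "q": "C", "v": "B"}, costs=costs,
        )

    return build


@pytest.fixture
def crossed_transfers():
    """Two transfers crossing between sibling host subtrees.

    Host a has children b and c; a gene node below c lands in the edge
    above b and a gene node below b lands in the edge above c, forcing
    "c before b" and "b before c" simultaneously: temporally infeasible.
    """
    inst = make_instance(
        "((B1,B2)b,(C1,C2)c)a;",
        "((x1,x2)x,(y1,y2)y)r;",
        {"x1": "C1", "x2": "B2", "y1": "B1", "y2": "C2"},
    )
    sc = DTLScenario(
        mapping={"x1": "C1", "x2": "B2", "y1": "B1", "y2": "C2",
                 "x": "C1", "y": "B1", "r": "a"},
        events={"x": "transfer", "y": "transfer", "r": "speciation"},
        transfer_edges={("x", "x2"), ("y", "y2")},
        landing={"x": "b", "y": "c"},
    )
    return inst, sc
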