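"""Selection, pull-up, the repair loop, and the best-of-N protocol."""

import pytest

from reconrepair import (
    DTLScenario,
    build_feasibility_graph,
    compute_tables,
    is_feasible,
    pull_up,
    repair,
    repair_best,
    scenario_cost,
    select_repair_node,
    traceback,
    validate_scenario,
)
from conftest import make_instance
from test_mpr import small_random_instances


class TestSelection:
    def test_acyclic_graph_selects_nothing(self, congruent_pair):
        sc = DTLScenario(
            mapping={"p": "A", "q": "B", "g": "r"},
            events={"g": "speciation"},
        )
        fg = build_feasibility_graph(congruent_pair, sc)
        assert select_repair_node(congruent_pair, sc, fg) is None

    def test_crossed_transfers_selects_lowest_mapped(self, crossed_transfers):
        inst, sc = crossed_transfers
        fg = build_feasibility_graph(inst, sc)
        g = select_repair_node(inst, sc, fg)
        # y maps to B1 (host post-order index 0), x maps to C1 (index 3)
        assert g == "y"
        # no cycle-bound gene node maps to a proper descendant of M(g)
        for other in ("x", "y"):
            assert inst.host.relate(sc.mapping[other], sc.mapping[g]) != "descendant"

    def test_selection_minimality_on_random_instances(self):
        """Every selection is a cycle-bound gene node such that no other
        cycle-bound gene node maps to a proper descendant of its mapping,
        and it is never mapped to the host root."""
        from reconrepair import (
            SimulationConfig,
            generate_instance,
            nodes_on_cycles,
        )

        selections = 0
        for seed in range(30):
            cfg = SimulationConfig(host_leaves=8, p_switch=0.35,
                                   p_duplication=0.08, p_loss=0.12, seed=seed)
            inst, _ = generate_instance(cfg)
            current = traceback(compute_tables(inst))
            while True:
                fg = build_feasibility_graph(inst, current)
                g = select_repair_node(inst, current, fg)
                if g is None:
                    break
                cycle_bound = nodes_on_cycles(fg)
                assert g in cycle_bound
                assert current.mapping[g] != inst.host.root
                for other in cycle_bound:
                    assert inst.host.relate(
                        current.mapping[other], current.mapping[g]
                    ) != "descendant"
                current = pull_up(inst, current, g)
                selections += 1
        assert selections >= 10


class TestPullUp:
    def test_speciation_becomes_duplication_in_place(self, congruent_pair):
        sc = DTLScenario(
            mapping={"p": "A", "q": "B", "g": "r"},
            events={"g": "speciation"},
        )
        out = pull_up(congruent_pair, sc, "g")
        assert out.events["g"] == "duplication"
        assert out.mapping["g"] == "r"
        # losses increase by exactly 2: (d-1)+(d-1) becomes d+d
        assert (scenario_cost(congruent_pair, out).total_losses
                - scenario_cost(congruent_pair, sc).total_losses) == 2

    def test_duplication_moves_to_parent(self):
        inst = make_instance("((A,B)x,C)r;", "(p,q)g;", {"p": "A", "q": "A"})
        sc = DTLScenario(
            mapping={"p": "A", "q": "A", "g": "A"},
            events={"g": "duplication"},
        )
        out = pull_up(inst, sc, "g")
        assert out.events["g"] == "duplication"
        assert out.mapping["g"] == "x"

    def test_transfer_conversion_depends_on_landing_comparability(self):
        inst = make_instance("((A,B)x,C)r;", "(p,q)g;", {"p": "A", "q": "B"})
        sc = DTLScenario(
            mapping={"p": "A", "q": "B", "g": "A"},
            events={"g": "transfer"},
            transfer_edges={("g", "q")},
            landing={"g": "B"},
        )
        out = pull_up(inst, sc, "g")  # new mapping x dominates landing B
        assert out.events["g"] == "duplication"
        assert out.mapping["g"] == "x"
        assert not out.transfer_edges and not out.landing

        inst2 = make_instance("((A,B)x,C)r;", "(p,q)g;", {"p": "A", "q": "C"})
        sc2 = DTLScenario(
            mapping={"p": "A", "q": "C", "g": "A"},
            events={"g": "transfer"},
            transfer_edges={("g", "q")},
            landing={"g": "C"},
        )
        out2 = pull_up(inst2, sc2, "g")  # x and C incomparable: stays a transfer
        assert out2.events["g"] == "transfer"
        assert out2.mapping["g"] == "x"
        assert out2.landing["g"] == "C"

    def test_preconditions(self, congruent_pair):
        sc = DTLScenario(
            mapping={"p": "A", "q": "B", "g": "r"},
            events={"g": "duplication"},
        )
        with pytest.raises(ValueError, match="leaf"):
            pull_up(congruent_pair, sc, "p")
        with pytest.raises(ValueError, match="root"):
            pull_up(congruent_pair, sc, "g")

    def test_co_mapped_parent_is_carried_along(self):
        """Pulling a node above a parent mapped to the same species node
        must raise the parent too, keeping the scenario valid."""
        inst = make_instance("((A,B)x,C)r;", "((p,q)w,v)g;",
                             {"p": "A", "q": "A", "v": "A"})
        sc = DTLScenario(
            mapping={"p": "A", "q": "A", "v": "A", "w": "A", "g": "A"},
            events={"w": "duplication", "g": "duplication"},
        )
        assert validate_scenario(inst, sc) == []
        out = pull_up(inst, sc, "w")
        assert validate_scenario(inst, out) == []
        assert out.mapping["w"] == "x"
        assert out.mapping["g"] == "x"  # parent pulled along

    def test_transferring_parent_landing_site_follows_child(self):
        """Pulling the transferred child above its landing site lifts the
        parent's landing site with it."""
        inst = make_instance("((A,B)x,C)r;", "((p,q)w,v)g;",
                             {"p": "A", "q": "A", "v": "C"})
        sc = DTLScenario(
            mapping={"p": "A", "q": "A", "v": "C", "w": "A", "g": "C"},
            events={"w": "duplication", "g": "transfer"},
            transfer_edges={("g", "w")},
            landing={"g": "A"},
        )
        assert validate_scenario(inst, sc) == []
        out = pull_up(inst, sc, "w")
        assert validate_scenario(inst, out) == []
        assert out.mapping["w"] == "x"
        assert out.landing["g"] == "x"  # site lifted to the child's mapping


class TestRepairLoop:
    def test_feasible_input_is_returned_unchanged(self, congruent_pair):
        sc = traceback(compute_tables(congruent_pair))
        fixed, trace = repair(congruent_pair, sc)
        assert fixed.canonical_key() == sc.canonical_key()
        assert trace.steps == []
        assert trace.initial_cost == trace.final_cost

    def test_crossed_transfers_fixed_in_one_step(self, crossed_transfers):
        inst, sc = crossed_transfers
        assert not is_feasible(build_feasibility_graph(inst, sc))[0]
        fixed, trace = repair(inst, sc)
        assert len(trace.steps) == 1
        assert trace.steps[0].gene_node == "y"
        assert is_feasible(build_feasibility_graph(inst, fixed))[0]

    def test_randomized_runs_obey_repair_guarantees(self):
        """Termination cap, validity after every step, final feasibility,
        additive event bounds, and the lower-bound property, on simulated
        switch-rich instances."""
        import random

        from reconrepair import SimulationConfig, SimulationError, generate_instance

        rng = random.Random(4242)
        n = 0
        seed = 0
        repaired_any = False
        while n < 60:
            seed += 1
            cfg = SimulationConfig(
                host_leaves=rng.randint(4, 10), p_switch=0.35,
                p_duplication=0.08, p_loss=0.12, seed=seed,
                max_parasite_leaves=32,
            )
            try:
                inst, _ = generate_instance(cfg)
            except SimulationError:
                continue
            tables = compute_tables(inst)
            sc = traceback(tables)
            was_feasible = is_feasible(build_feasibility_graph(inst, sc))[0]
            fixed, trace = repair(inst, sc)
            assert validate_scenario(inst, fixed) == []
            assert is_feasible(build_feasibility_graph(inst, fixed))[0]
            assert len(trace.steps) <= trace.step_cap
            assert trace.added_duplications <= trace.duplication_bound
            assert trace.added_losses <= trace.loss_bound
            assert trace.final_cost >= tables.optimal_cost
            if was_feasible:
                assert trace.final_cost == tables.optimal_cost
                assert not trace.steps
            else:
                repaired_any = True
            n += 1
        assert repaired_any

    def test_every_intermediate_scenario_is_valid(self):
        """Replay a repair step by step: validity holds after each pull-up."""
        from reconrepair import SimulationConfig, generate_instance

        replayed = 0
        for seed in range(40):
            cfg = SimulationConfig(host_leaves=8, p_switch=0.35,
                                   p_duplication=0.08, p_loss=0.12, seed=seed)
            inst, _ = generate_instance(cfg)
            sc = traceback(compute_tables(inst))
            current = sc
            while True:
                fg = build_feasibility_graph(inst, current)
                g = select_repair_node(inst, current, fg)
                if g is None:
                    break
                current = pull_up(inst, current, g)
                assert validate_scenario(inst, current) == []
                replayed += 1
        assert replayed >= 5

    def test_trace_json_is_complete(self, crossed_transfers):
        import json

        inst, sc = crossed_transfers
        _, trace = repair(inst, sc)
        payload = json.loads(trace.to_json())
        assert payload["initial_transfers"] == 2
        assert len(payload["steps"]) == 1
        assert payload["steps"][0]["gene_node"] == "y"
        assert payload["final_cost"] >= payload["initial_cost"]


class TestRepairBest:
    def test_feasible_mpr_hits_lower_bound(self, congruent_pair):
        best, report = repair_best(congruent_pair, n=10)
        assert report.candidates[report.best_index].post_repair_cost == report.lower_bound
        assert scenario_cost(congruent_pair, best).total_cost == report.lower_bound

    def test_feasible_co_optimum_dominates(self):
        """With ties between a feasible and other optima, the returned
        scenario is feasible and meets the lower bound."""
        inst = make_instance("((A,B)x,C)r;", "(p,q)g;",
                             {"p": "A", "q": "C"}, costs=(2, 1, 1))
        best, report = repair_best(inst, n=10)
        assert is_feasible(build_feasibility_graph(inst, best))[0]
        assert scenario_cost(inst, best).total_cost == report.lower_bound

    def test_n_one_equals_repairing_the_traceback(self):
        for inst in small_random_instances(8, base_seed=88):
            best, report = repair_best(inst, n=1)
            sc = traceback(compute_tables(inst))
            fixed, _ = repair(inst, sc)
            assert best.canonical_key() == fixed.canonical_key()
            assert len(report.candidates) == 1

    def test_report_costs_bound_each_other(self):
        for inst in small_random_instances(10, base_seed=31):
            _, report = repair_best(inst, n=10)
            for cand in report.candidates:
                assert cand.pre_repair_cost == report.lower_bound
                assert cand.post_repair_cost >= cand.pre_repair_cost
                assert cand.was_feasible == (cand.n_steps == 0)
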