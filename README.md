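# reconrepair

Temporally feasible maximum-parsimony DTL reconciliation of undated
host/parasite (or species/gene) trees.

## The problem

Phylogenetic tree reconciliation explains the incongruence between a host
tree *S* and a parasite tree *G* (tied together by a leaf-association map)
as a series of discrete events: **cospeciation** (the parasite diverges
with its host; cost 0), **duplication** (it diverges on one host lineage;
cost *C*<sub>Δ</sub>), **transfer** / host switch (one daughter lineage
jumps to a contemporaneous, non-ancestral host; cost *C*<sub>Θ</sub>), and
**loss** (cost *C*<sub>Λ</sub>). A *maximum parsimony reconciliation*
(MPR) minimizes the total weighted event count

&nbsp;&nbsp;&nbsp;&nbsp;*C*<sub>Δ</sub>·|Δ| + *C*<sub>Θ</sub>·|Θ| + *C*<sub>Λ</sub>·Loss

over all valid mappings of *G* into *S*. When the internal nodes of *S*
are undated, an MPR can be found in O(|G|·|S|) time by dynamic
programming — but the result may be *temporally infeasible*: two host
switches can impose contradictory "before" constraints on the host tree's
internal nodes, so that no dating of *S* is consistent with all events.
Finding a least-cost reconciliation that is also feasible is NP-complete.

`reconrepair` implements a fast heuristic with a useful guarantee chain:

1. compute an MPR (its cost is a *lower bound* for every feasible
   reconciliation);
2. test it for temporal feasibility by building a directed constraint
   graph over the internal nodes of both trees — the reconciliation is
   feasible iff the graph is acyclic, and a topological order of the
   acyclic graph is a feasible dating of the host tree;
3. if the graph has cycles, *repair* the reconciliation: repeatedly pick a
   lowest-mapped gene node on a cycle and pull it one level up the host
   tree (cospeciation → duplication in place; duplication → parent host
   node; transfer → parent host node, collapsing into a duplication if it
   overtakes its landing site), until the graph is acyclic.

The repair loop always terminates, keeps the reconciliation valid after
every step, and adds at most *k·h*<sub>G</sub> duplications and
*k·h*<sub>G</sub>·*h*<sub>S</sub> losses, where *k* is the number of
transfers in the input MPR and *h*<sub>G</sub>, *h*<sub>S</sub> are the
tree heights. Because several co-optimal MPRs usually exist, the default
protocol enumerates the first 10, repairs each, and reports the best.

## Worked example

Host `((A,B)x,C)r`, parasite `((p,q)w,v)g`, associations `p→A, q→C, v→B`:
the parasite tracked the host everywhere except one jump. With duplication
and loss at cost 1 and transfer at cost 5:

```
$ reconrepair reconcile --host host.nwk --parasite parasite.nwk --map map.tsv \
      --dup 1 --transfer 5 --loss 1 --mprs 10
{
  "lower_bound": 4.0,
  "best_cost": 4.0,
  "events": {
    "speciations": 1,
    "duplications": 1,
    "transfers": 0,
    "losses": 3
  },
  ...
  "feasible_dating": ["r", "x"]
}
```

The transfer is priced out, so the optimum explains the data as a
speciation at the host root plus an earlier duplication with three losses:
total cost 4. The reconciliation is already feasible (`"was_feasible":
true`, zero repair steps), `best_cost` equals the lower bound — so this is
provably optimal among feasible reconciliations — and the dating orders
host node `r` before `x`. Rerun with `--transfer 1` and the optimum
becomes one cospeciation plus one host switch at cost 1.

The other subcommands: `reconrepair check` validates a scenario JSON and
tests its feasibility; `reconrepair simulate` generates seeded synthetic
coevolution instances (random host tree; parasite evolving down it with
configurable duplication / host-switch / loss probabilities).

## Library surface

```python
from reconrepair import (
    parse_newick, ProblemInstance, EventCosts,          # inputs
    compute_tables, traceback, enumerate_mprs,          # parsimony DP
    build_feasibility_graph, is_feasible, feasible_dating,
    repair, repair_best,                                # the repair loop
    generate_instance, SimulationConfig,                # simulator
    brute_force_mpr, brute_force_feasibility,           # test oracles
)
```

See `docs/methods.md` for the model, the constraint-graph rules, the
repair guarantees, and the numerical/design choices.

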