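# Methods

## The reconciliation model

Both input trees must be rooted, binary, and undated; leaves of the
parasite tree *G* are mapped (not necessarily injectively) onto leaves of
the host tree *S*. A reconciliation is described by:

* a node map **M** : V(G) → V(S) extending the leaf association;
* a partition of the internal nodes of *G* into **speciation**,
  **duplication**, and **transfer** nodes;
* the set of **transfer edges** — gene edges whose endpoint images are
  incomparable in *S* (this is forced: an edge is a transfer edge *iff*
  its images are incomparable); each internal node carries at most one;
* a **landing site** τ(g) for each transfer node — the host node whose
  incoming edge receives the transferred lineage; it must be incomparable
  to the takeoff mapping M(g) and must dominate the transferred child's
  image.

Validity further requires that a node's image is never strictly below a
child's image, that at least one child's image lies in its image's
subtree, that a speciation sits exactly at the LCA of its (incomparable)
child images, and that a duplication sits at or above that LCA.
`validate_scenario` checks all of this and returns the full list of
violations, each naming the offending gene node, rather than failing
fast — scenarios produced by hand or read from JSON get a complete
diagnosis in one pass.

Losses are inferred per internal gene node from path lengths in *S*:
`(d(M(g),M(gl))−1) + (d(M(g),M(gr))−1)` at a speciation and
`d(M(g),M(gl)) + d(M(g),M(gr))` at a duplication. At a transfer with
transferred child g′, the count is `d(M(g),M(other)) + d(τ(g),M(g′))` —
the stay-side distance is charged in full (no −1) and the landing side is
charged from the landing site, not from M(g). The transfer rule is
asymmetric with the speciation rule by definition; it is implemented
exactly as defined, and the cost returned by `scenario_cost` is

    C_dup · #duplications + C_transfer · #transfers + C_loss · #losses

with speciations free. All three costs must be strictly positive.

## The parsimony dynamic program

`compute_tables` fills `c(g, s)` — the minimum cost of reconciling the
gene subtree at g with g mapped exactly to s — bottom-up over G, with
three auxiliaries that make each cell O(1) amortized (post-order over S
for `inn` and `best`, pre-order for `out`):

* `inn(g, s)` = min over s′ ≤ s of `c(g, s′) + C_loss · d(s, s′)`;
* `best(g, s)` = min over s′ ≤ s of `c(g, s′)` (no loss surcharge);
* `out(g, s)` = min over s′ incomparable to s of `c(g, s′)`.

A speciation at internal s with children x, y costs
`min(inn(g1,x)+inn(g2,y), inn(g1,y)+inn(g2,x))`; a duplication costs
`C_dup + inn(g1,s) + inn(g2,s)`; a transfer costs
`C_transfer + min(inn(g1,s)+out(g2,s), inn(g2,s)+out(g1,s))`. The
transferred child is charged through `out`/`best` with no loss surcharge
because the traced landing site is the transferred child's own mapping
node — the unique choice with zero landing-side losses permitted by the
landing constraint — so the table value equals the event-based cost of
every traced scenario exactly (asserted in the tests and in the
acceptance script). The optimum `min_s c(rt(G), s)` lower-bounds the cost
of *every* valid reconciliation, feasible or not.

Numerical choices:

* All DP arithmetic uses `fractions.Fraction`. Decimal cost inputs are
  converted through their string form (`0.1 → 1/10`), which is exactly the
  common-denominator integer rescaling, so tie detection during co-optimal
  enumeration is exact for every cost vector a user can type; no floating
  tolerance exists anywhere in the package.
* "Unreachable" cells hold a finite sentinel strictly larger than any
  achievable cost (`(C_dup + C_transfer + 2·C_loss·|V(S)|) · |I(G)| + 1`),
  so `min()` needs no special cases; the sentinel never escapes into
  reports.

`enumerate_mprs` walks the traceback choice points depth-first in a fixed
order — root placements in host post-order; at each cell, speciation
before duplication before transfer; left-child assignments before right;
placement at the current host node before descent into its children — so
enumeration order is deterministic and `traceback` is simply its first
element. Expansions from distinct choice points differ structurally, so
the enumerated scenarios are pairwise distinct by construction (a seen-set
guards the contract anyway). The order is a convention of this package;
only determinism, validity, and optimality of every enumerated scenario
are contractual.

## The temporal feasibility graph

A reconciliation of undated trees is feasible iff the internal host nodes
can be totally ordered consistently with every event. The test builds a
directed graph whose vertices are the internal nodes of both trees plus a
single sink representing all leaves, and whose edges mean "must be dated
earlier":

1. parent → child for internal tree edges in either tree, and
   node → sink for every parent of a leaf;
2. a speciation gene node is *identified* with its host node (merged into
   that vertex) — a cospeciation happens exactly at its host divergence;
3. a duplication at s lies strictly inside the host edge above s:
   pa(s) → g (omitted at the host root) and g → s;
4. a transfer's takeoff and landing are contemporaneous, so the event
   lies strictly inside both host edges: pa(s) → g, g → s, pa(s′) → g,
   g → s′ for landing site s′.

Edge endpoints that are host leaves are redirected to the sink (the
vertex set deliberately contains no individual leaves — nothing is ever
constrained to happen *after* a leaf), parallel edges collapse to one
with the union of producing rules attached (useful for explaining
cycles), and the scenario is validated before construction, which rules
out self-loops. The reconciliation is feasible iff this graph is acyclic
(`is_feasible` also returns a concrete cycle when not); a lexicographic
topological sort restricted to the host vertices gives a deterministic
feasible dating (`feasible_dating`), ties broken by host post-order
index. The test fixes each transfer's landing site as given in the
scenario; it does not search over alternative landing sites, so a
scenario can be reported infeasible even if relocating a landing site
would rescue it — such a relocation would describe a different
reconciliation.

Only the host-node order is reported as the dating: the relative dates of
duplication and transfer events inside their host edges are implied by
the graph but are not part of the host tree's dating.

## The repair loop

`select_repair_node` scans the internal gene nodes sorted by the host
post-order index of their mapping (ties by gene post-order index) and
returns the first whose graph vertex lies in a strongly connected
component with at least two vertices — i.e. a cycle-bound gene node such
that no other cycle-bound gene node is mapped to a proper descendant of
its mapping. Identified speciation vertices count as cycle-bound under
their gene identity. Cycle membership is recomputed from scratch each
iteration via one SCC pass (same answer as per-node DFS, better
constant). A gene node mapped to the host root can never be selected:
nothing outside the root-mapped vertex set points into it, and within the
set only gene-ancestry edges exist, so those vertices never lie on
cycles.

`pull_up` raises the selected node one level: a speciation becomes a
duplication at the same host node (its first pull does not move it); a
duplication moves to the parent host node; a transfer moves to the parent
host node and collapses into a duplication — dropping its transfer edge
and landing site — if the new mapping strictly dominates the landing
site, and keeps them otherwise.

The single-node rule alone does not always leave a valid scenario: when
the raised image overtakes the gene parent's placement, the violation
appears *at the parent*. Two configurations arise, and `pull_up` resolves
both with the minimal rootward cascade, so that its output is
unconditionally valid:

* the parent is mapped to the same host node (a co-mapped duplication or
  transfer, or a speciation whose child image caught up with it): the
  parent is itself pulled one level at a time until it is no longer below
  the raised child, and the adjustment then propagates to *its* parent if
  needed;
* the parent transferred the raised node and its landing site no longer
  dominates the child's image: the landing site is lifted to the child's
  new mapping (the only choice that keeps the landing constraint with
  zero landing-side losses); if that makes takeoff and landing comparable
  the parent's transfer collapses into a duplication at the child's
  mapping, and the cascade continues upward.

Every cascade step only moves mappings upward, so it terminates; apart
from these forced adjustments, landing sites are never revisited.

`repair` alternates graph construction, selection, and pull-up until the
selector returns nothing, validating (and re-costing) the scenario after
every step; an already-feasible input is returned unchanged with an empty
trace. Guarantees, all checked on every randomized test run:

* **termination** within `|I(G)| · (h_S + 1)` selections — each node is
  selected at most once per host level plus once for its in-place
  speciation→duplication conversion; the cap is enforced and exceeding it
  is treated as an internal error;
* **validity** after every step;
* **feasibility** of the final scenario;
* **bounded damage**: at most `k·h_G` added duplications and
  `k·h_G·h_S` added losses relative to the input reconciliation, where k
  is the input's transfer count (each node converts to a duplication at
  most once, and each conversion adds at most `h_S`-ish losses; the bound
  is loose — the randomized sweeps never exceed half of it);
* **the lower-bound property**: the final cost is never below the
  parsimony optimum, with equality exactly when no repair was needed.

One property that might be expected does *not* hold: a selected node need
not have a transfer among its gene-tree descendants. A speciation's
identified vertex can lie on a cycle driven entirely by transfers in
unrelated parts of the gene tree, and the selection rule (correctly)
picks it; pulling it detaches it from the cycle's host vertex. What is
true, and tested, is the weaker structural fact that every cycle contains
at least one transfer-placement arc: deleting all rule-4 transfer edges
always leaves the graph acyclic, because all remaining edges point "down"
the two trees.

`repair_best` enumerates the first *n* co-optimal reconciliations
(default n = 10), repairs each, and returns the cheapest result, ties
broken by enumeration order; its report lists every candidate's pre- and
post-repair cost next to the shared lower bound, so optimality of the
answer is certified whenever some candidate needed no repair.

## The simulator

`generate_instance` grows a host tree by uniform random joins of leaf
lineages, then evolves parasite lineages down it. At each internal host
node a lineage draws one event: duplication (probability `p_duplication`,
both copies stay), host switch (`p_switch`, one copy jumps to a uniformly
chosen incomparable host node), or cospeciation (the rest; the two
daughters follow the two host children, each dying en route with
probability `p_loss`). Lineages reaching host leaves become parasite
leaves; extinct sides collapse their parent node, and instances whose
parasite goes extinct, degenerates to a single leaf, or exceeds the size
cap are regenerated (bounded retries, then a hard error suggesting a
lower loss rate). All randomness flows through one explicitly passed
seed; equal configs give bit-identical instances.

Defaults (8 host leaves, duplication 0.05, switch 0.3, loss 0.1, costs
2/3/1) sit in the switch-rich regime where temporally infeasible optima
actually occur — roughly a third of the sweep instances in the acceptance
suite need repair. The model emulates codivergence with host switching
only: no switch-back-to-ancestor variants, no rate heterogeneity across
lineages or time, no failure-to-diverge, no sampling noise in the leaf
associations. Passing tests therefore demonstrate algorithmic
correctness on transfer-rich coevolutionary histories, not calibration
to any real dataset.

## Test oracles and problem sizes

Two deliberately naive oracles cross-check the production paths and are
never used by them:

* `brute_force_mpr` enumerates every valid node map (the transfer edges
  and admissible event labels are then forced or locally enumerable) and
  scores each scenario by the loss/cost definitions directly; because the
  cost decomposes over internal gene nodes for a fixed map, per-node
  minimisation inside each map yields the exact optimum and the complete
  optimal set. Guarded to ≤ 5 leaves per tree.
* `brute_force_feasibility` tries every ancestry-consistent total order
  of the internal host nodes and greedily schedules event times
  (speciations pinned to their host node's date; duplications strictly
  inside the host edge above their mapping; transfers at a common time
  strictly inside takeoff and landing edges; parent events strictly
  before child events), using exact lexicographic (rank, ε) time values.
  Earliest-first scheduling is optimal here because relaxing any event
  time only loosens its descendants' constraints. Guarded to ≤ 8 internal
  nodes across both trees.

The standard suite sizes, chosen to keep the full run near ten seconds
while exercising every guarantee: 200 oracle-equivalence instances with
≤ 5 leaves per tree and integer costs in [1, 5]; 500 switch-rich repair
instances with 4–12 host leaves (parasites capped at 32 leaves); the
hand-built crossed-transfer regression (two transfers between sibling
host subtrees forcing contradictory datings — infeasible, repaired by
exactly one pull-up).

## Known limitations

* The repair is greedy; it certifies optimality only when some co-optimal
  reconciliation needs no repair. No search over repair orders or landing
  relocations is attempted, and the additive bounds above are loose.
* Host switches are the only cycle source modelled; "transfer from the
  dead" (switching from an extinct/unsampled donor) is out of scope, as
  are non-binary trees, dated hosts, and per-branch event costs.
* The count of co-optimal reconciliations is not computed beyond the
  enumeration limit.
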