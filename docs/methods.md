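# Methods

## Problem and model

Given a rooted tree `T = (X, N, B)` — leaves `X` carrying extant
sequences, internal nodes `N`, branches `B` with the parent written
first — and an MSA of the leaves reduced to a binary matrix
(`a_ki = 1` iff row `k` has a residue at site `i`), the task is the
small parsimony problem on whole gap patterns: assign every internal
node a binary pattern minimizing an affine indel cost summed over
branches. Node indexing follows the convention root = 1, remaining
internal nodes 2..|N| breadth-first, leaves |N|+1.. breadth-first, so
every branch satisfies parent-index < child-index. Sites are 1-based;
a dummy start site 0 and end site m+1 carry state 1 in every sequence,
which removes boundary cases for terminal gaps.

Column preprocessing is lossless for inference: columns gapped in
every row are removed (they are recorded separately so output can be
expanded back to original coordinates), and each maximal run of ≥ 2
*originally consecutive* all-occupied columns collapses to one site.
An optional stronger reduction collapses runs of columns with
identical binary pattern; it is off by default because it changes the
per-site cost accounting.

The POAG is the union over rows of edges between consecutive occupied
sites (plus dummy edges). Ancestors are constrained to start→end
paths in this graph, which is exactly the statement that an ancestor's
indel arrangement must be assembled from arrangements witnessed in the
extant data.

### The MIP

Variables (all binary): `a_ki` for internal `k` and real sites `i`;
`y_kp` per internal node and POAG edge; `d_bi`, `g_bi` per branch and
site. Constraints:

* flow: at every real site, in-edge sum = `a_ki` = out-edge sum; unit
  flow out of the dummy start and into the dummy end. Together these
  make each ancestor's selected edges one start→end path whose visited
  sites are its 1-states.
* differences: `d_bi = |a_ki − a_li|` linearized from **both** sides —
  `d ≥ ±(a_k − a_l)` and `d ≤ a_k + a_l`, `d ≤ 2 − a_k − a_l`. The
  upper bounds are not redundant: the opening constraint at site i+1
  contains `−d_bi`, so a `d` free to float up at cost 1 could pay for
  itself by suppressing an opening at cost α > 1. With the equality
  enforced, `d` is what it claims to be and the objective decomposes
  per branch.
* openings: `g_b1 = d_b1`; `g_bi ≥ d_bi − d_b(i−1)` (a run of
  differences starts); and two reversal bounds
  `g ≥ a_k(i−1) + a_li − a_l(i−1) − a_ki − 1` and its mirror, which
  force an opening when both sequences change state while remaining
  different — an insertion directly abutting a deletion is two events,
  as in affine-gap pairwise alignment. Since `g` has a positive
  objective coefficient in a minimization, lower bounds suffice.

Objective: `Σ_b Σ_i (d_bi + α g_bi)`. α (default 2) prices opening an
event relative to extending one; the optimal objective is
non-decreasing and the opening count non-increasing in α (tested as a
trend).

Leaves contribute constants, not variables; their states fold into the
constraint bounds.

### Solver

The model is solved with HiGHS through `scipy.optimize.milp`, as one
sparse `LinearConstraint` (CSR) with equality rows expressed as equal
lower/upper bounds. Defaults: one solver thread, 3600 s time limit,
relative MIP gap 0. On time-limit the incumbent is returned with
status `feasible_time_limit` and the reported gap. Every returned
solution is re-verified independently of the solver: selected edges
must form one POAG path per ancestor and the objective is recomputed
from the patterns (tolerance 1e−6); any discrepancy raises rather
than returning a silently wrong solution.

### Alternative optima

Enumeration repeatedly re-solves with (i) the objective pinned to the
first optimum (equality within 1e−6 — the no-good cut alone would not
preserve optimality) and (ii) one no-good cut per found solution,
`Σ_{edges selected} y ≤ Q − 1`, which excludes exactly that edge
assignment and nothing else. The loop stops at infeasibility (ties
exhausted) or at `max_alternatives`. Which optimum HiGHS returns
first is not normalized; determinism of reported output comes from
sorting solutions lexicographically by concatenated ancestral
patterns.

### Brute-force oracle

For small instances an exhaustive check enumerates every assignment of
POAG paths to internal nodes (capped, default 10^6 assignments). Costs
decompose over branches, so the oracle precomputes a path×path cost
table once and broadcast-sums it over one tensor axis per ancestor;
all argmin assignments are returned. The oracle shares only the
pattern-pair scoring function with the MIP — not the model or solver —
and the suite asserts exact agreement on hundreds of random instances
(3–5 leaves, 3–8 sites).

## Metrics

* **Indel events per branch**: a site counts as an event iff the two
  patterns differ there and at least one of the two changed state
  relative to the previous site (virtual site 0 = state 1, so a site-1
  difference always opens). This equals `Σ g` of the affine scoring,
  a property-tested identity. The **indel score** sums events over all
  branches; the root contributes only via its outgoing branches.
* **Evolutionary cohesiveness**: an ancestor is incohesive if at some
  site its state differs from its parent's and from every child's —
  content blinking in or out for a single generation, which is
  biologically implausible. Eligible nodes are internal nodes with a
  parent; percentages are over eligible nodes, one decimal.
* **Footprint conformity**: an ancestor is non-conforming if its
  pattern's edge path uses an edge absent from the extant POAG. MIP
  solutions conform by construction (their edges are POAG variables);
  the per-column baseline can violate it because columns are called
  independently. An all-gap ancestral pattern is reported as
  degenerate rather than erroring.
* **Truth comparison** (simulation only): per-ancestor Hamming
  distance and exact-match counts, computed in original alignment
  coordinates.

## PSP baseline

Per-column Fitch parsimony: bottom-up candidate sets
(intersection/union), top-down resolution preferring the parent's
state, ambiguous root → 1 (residue present). The tie-break is
deterministic and configurable; with a single consistent resolution
PSP stays column-cohesive, and its per-column change count is exactly
the Fitch minimum — which also lower-bounds the `Σ d` of any
whole-pattern assignment, including the MIP optimum (a tested
invariant). PSP's weakness is structural, not numerical: assembling
independently called columns into sequences can produce indel
arrangements no extant sequence has.

## Simulator

The generator emulates indel evolution down a random tree:

* **Topology**: repeatedly bifurcate a uniformly chosen current tip
  until `n` leaves exist.
* **Branch lengths**: Gamma(κ, θ = 0.2) draws, rescaled once so the
  mean root-to-leaf path equals δ (the alternative, normalizing the
  mean branch length, was considered and rejected because the study
  conditions are stated as mean distance from the root).
* **Indel process**: root starts all-occupied with 200 sites; on a
  branch of length t, the event count is Poisson(rate · t · L/200)
  with L the current residue count (rate default 1 event per unit
  distance for a root-length sequence); each event is an insertion or
  deletion with probability ½, geometric length (mean 3), uniform
  position. Insertions open new global columns, gapped everywhere
  outside the subtree below the event, so the emitted alignment is
  perfect by construction. A deletion that would empty a sequence is
  truncated to leave one residue (logged).
* **Coordinates**: columns with no residue in any extant are dropped
  from the alignment *and* from all recorded patterns, so the recorded
  truth is the observable history; events that left no extant trace
  (e.g. an insertion later deleted everywhere) are not representable
  as columns and are excluded from the truth score. Consequently the
  inferred optimum can legitimately score at or below the truth.

Defaults (n, δ, κ, θ, root length, rates) are the package's stated
study conditions; a single integer seed fixes tree, events and output
byte-for-byte (independent sub-streams for topology and events).

What the simulator does **not** emulate: amino-acid substitution (only
gap structure is generated), alignment error (real MSAs are estimated,
so real gap patterns carry aligner artefacts), rate variation across
sites or lineages, and overlapping-event ambiguity beyond what the
observable-coordinate convention captures. Passing tests on simulated
data therefore demonstrate correctness of the inference given a
correct alignment, not robustness to misalignment.

## Numerical and scale choices

* All variables are declared binary; relaxing `d`/`g` to [0,1] is
  likely valid but untested, and binaries are cheap here.
* Objective comparisons use absolute tolerance 1e−6 (solver
  integrality makes true values integral for integral α).
* Infeasibility of the base model is impossible (copying any extant
  footprint to every ancestor is feasible) and is treated as an
  internal error.
* Test and battery sizes — 50-leaf simulations with 200-site roots,
  200 oracle instances at 3–5 leaves — were chosen so the full suite
  runs in well under half an hour on one CPU while still exercising
  nontrivial POAGs (dozens of reduced sites, tens of thousands of MIP
  variables).

## Known limitations

* Parsimony only: branch lengths are parsed and preserved but ignored;
  no likelihood model of indel evolution is provided.
* One gap character class: ambiguity codes and case conventions beyond
  `-`/`.` are the caller's responsibility.
* Scaling is empirical: thousands of sequences solve in practice, but
  MIP worst cases are exponential and very large trees may time out,
  returning an incumbent with a reported gap.
* Multifurcations are supported (opt-in) by the model, which only
  needs the branch set, but the strict-bifurcation default guards
  against accidentally unrooted inputs.
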