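# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `grnbench`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Graphs, signs, and conventions

Networks are simple directed graphs (no parallel edges; self-loops
allowed, since a gene may regulate itself and length-1 feedback loops are
scored).  "Connected" means *weakly* connected: strong connectivity would
forbid external parameters, which must exist.  An **external parameter**
is a node with in-degree 0; it carries no update function and copies its
own state, so the state space splits into `2^(#external)` invariant
slices and attractor counts are reported for the whole network (all
slices combined).  Node labels are opaque strings; internal indexing is
0-based, and configurations are packed as integers with node 0 in the
least significant bit.

All distribution comparisons use the total-variation (half-L1) distance
on normalised histograms.  It is bounded in [0, 1], symmetric, satisfies
the triangle inequality, is invariant to zero-padding of the support, and
needs no density-estimation hyperparameters.

## Motif census

**Signed FFL types.**  The 8 sign assignments of an FFL `(u, v, w)` split
into 4 coherent (direct edge sign equals the product of the two path
signs) and 4 incoherent types.  The field has no universal numbering, so
this package fixes one: sign triples `(sigma(u,v), sigma(v,w),
sigma(u,w))` in lexicographic order with `+` before `-`, coherent types
numbered 1–4 and incoherent 5–8 (type 1 is the all-activating coherent
FFL).  Target vectors must use the same convention; the fit is
order-consistent as long as they do.

**FFL clusters.**  Pairs of FFLs sharing exactly one node fall into 6
isomorphism classes of their union graph (motifs 1–6), pairs sharing an
edge into 6 more (motifs 7–12); a 3-node set carrying exactly two FFLs is
motif 13 or 14 and exactly three FFLs motif 15.  Within each overlap
class, motif ids follow the lexicographically smallest flattened
adjacency matrix of the union graph over all node permutations (brute
force; union graphs have at most 5 nodes).  Two configurations fall
outside this taxonomy and are tallied under key 0 rather than silently
dropped or misfiled: pairs sharing two nodes *without* a shared edge
(they require a 2-cycle between the shared nodes), and 3-node sets whose
complete digraph carries six FFLs.  Counting is per unordered FFL pair
for motifs 1–12 and per 3-node set for motifs 13–15, so a three-FFL
cluster is not additionally double-counted as three pairs.

**Feedback loops** are enumerated as simple directed cycles up to length
6 by default (the length range over which sign fractions are fitted),
rotation-normalised to start at their smallest node label.

## Topology generation

The underlying topology is fitted to five targets: out-degree power law
`P(k) ~ k^-gamma` on the finite support `[k_out_min, n-1]` (normalised by
explicit summation, no continuous approximation), truncated-Poisson
in-degree, the 15-bin FFL-cluster frequency vector, average connectivity,
and the external-parameter count.  Defaults: `n = 20`, `<k> = 2.5`
(hence 50 edges), one external parameter, `gamma = 2.0`, `k_out_min = 1`.
The Poisson rate is not separately tabulated anywhere authoritative, so
it defaults to the mean connectivity (2.5), which is the natural moment
match; it is configurable.

The search is deliberately simple and reproducible:

1. **Initial draw** — out-degrees sampled from the truncated power law;
   targets drawn uniformly among non-external nodes without duplicating
   edges.  Any non-designated node that lands on in-degree 0 receives one
   random regulator so the external count is exact from the start.
2. **Repair** — random legal adds/deletes until the edge count is exactly
   `round(n * <k>)` and the graph is weakly connected; deletes avoid
   removing a node's last regulator.
3. **Hill-climb** — feasibility-preserving rewires (one endpoint of a
   random edge moves; external nodes never gain regulators, regulated
   nodes never lose their last one, weak connectivity is rechecked), each
   accepted iff it strictly lowers the weighted total score.  The
   accepted-score trace is therefore strictly decreasing, and the hard
   constraints (50 edges, one external parameter, connectivity) hold for
   every returned graph regardless of whether the soft distribution score
   reaches the convergence tolerance.

Score weights default to 0.2 per component; the convergence tolerance on
the total (0.02) is rarely reached at n = 20 — empirical histograms of 20
nodes cannot match smooth target pmfs arbitrarily well — so runs normally
exhaust the iteration budget (default 4000 iterations, 2 restarts,
roughly 40 s on one core) and return the best graph found with
`converged=False`.  That is expected behaviour, not failure; the
distribution fit improves monotonically and the hard contracts always
hold.  `propose_modification` also exposes add/delete moves (bounded to
±10% of the target edge count) for callers running unconstrained
searches.

## Sign optimization

Per kingdom the objective is `w_FFL * ffl_err + w_FBL * fbl_err +
w_indeg * indeg_err` with default weights 1/3 each, where `ffl_err` is
the total-variation distance between realised and target FFL-type
distributions, and the FBL and in-degree components are mean absolute
fraction errors over *occupied* bins only (a network with no 5-cycles is
not penalised for the length-5 bin; the alternative of penalising absent
bins would push the topology stage, not the sign stage).  In-degrees
beyond the tabulated target range use the largest tabulated bin.

Stage 1 draws `pool_size` (default 5000; exhaustive when the FFL edge set
is small enough) random signings of the FFL edges and keeps the
`n_candidates = 25` best by `ffl_err`.  Stage 2, per candidate, repeats
`n_iterations = 1000` times per `(M, L)` pair: free (non-FFL) edges are
randomly signed until `M` remain open (one random draw per iteration),
`L` FFL edges are reopened by importance-weighted draw without
replacement — importance proportional to the inverse of the number of
FFLs an edge participates in, the simplest monotone version of
"rarely used edges are more likely" — and all `2^(M+L)` assignments of
the open edges are evaluated.  The default grid is `{(4,2), (6,3), (8,4),
(10,5)}` under a hard `M + L <= 20` cap.  The iteration count applies per
grid pair and is configurable.  Evaluation counts per exhaustive pass are
recorded for audit (`2^(M+L)` each), and on instances small enough to
enumerate completely the result provably equals the global optimum (see
the optimality tests).  Ties everywhere resolve to the lexicographically
smallest sign vector (`+` before `-`), and each seed candidate is
completed with an independent child RNG stream, so results are
deterministic and independent of the order in which kingdoms are run.

The full default budget (25 seeds x 1000 iterations x 4 grid pairs, up to
2^15 evaluations per pass) is the production setting for building a
released model set and runs for hours; the test suite and the acceptance
script exercise the same code paths at reduced budgets (a few seeds, a
handful of iterations, `M + L <= 6`), which the optimality and audit
tests show is sufficient to verify correctness.

### Kingdom target vectors

The kingdom-specific vectors (FFL-type frequencies, positive-FBL
fractions by length, activator fractions by in-degree) are inputs from
meta-analytic studies of real GRN models and are supplied through the
configuration file.  The shipped defaults are fixed illustrative
stand-ins chosen once from well-established qualitative regularities —
the all-activating coherent FFL type dominates, feedback loops are
enriched for inhibitory edges (positive fraction decreasing with length),
and the activator fraction decreases with in-degree — with mild
between-kingdom variation (e.g. bacteria most activator-rich).  They make
the pipeline runnable end-to-end out of the box; users reproducing a
specific published analysis should replace them with their own empirical
estimates via `grnbench config-dump` and `--config`.

## Canalizing rules

A function is canalizing if some input value forces the output; nesting
this recursively gives the canalizing depth, and *fully canalizing* means
depth equals in-degree.  `canalizing_depth` computes the maximal chain
length by recursive truth-table testing over all (variable, input) pairs,
memoised; constants return 0.

All three families are represented as nested canalizing chains
`[(variable, canalizing input a, canalized output b), ...]` (first match
decides; if nothing matches, the output is the complement of the last
`b`).  Sign consistency forces `a = b` for activators and `a = 1 - b` for
inhibitors, which makes every generated function monotone in each input
with the direction of its edge sign; every input stays essential because
the deeper chain always attains a value different from the current
canalized output.  OR-NOT sets every `b = 1` (disjunction of signed
literals); AND-OR-NOT chooses per node between all-`b=0` (conjunction)
and all-`b=1`, by a seeded Bernoulli(1/2) coin unless configured; the
general family draws a random input order and groups consecutive
variables into layers with geometric(1/2) sizes and alternating canalized
outputs, which mixes AND- and OR-like levels.  Any layer-size
distribution satisfying the invariants would do; this one is documented
and seeded.  Every constructed function is verified (full depth, sign
consistency) before a network is returned, and constants are disallowed
so all update rules remain regulatory.

External parameters evolve by identity.  The publication-style attractor
tables therefore count attractors over the whole state space; each
attractor lives within one fixed external-parameter value.

## Attractor analysis

Enumeration is exhaustive and exact, not sampled and not symbolic: the
successor of every configuration is computed vectorised (numpy, per-node
truth-table gather), the functional graph is peeled from its in-degree-0
states, the remaining states form the attractor cycles (in a functional
graph the cycle length *is* the minimal period), and basin membership is
propagated back through the peel order.  Basin sizes always sum to `2^n`.
At the benchmark size `n = 20` (about 10^6 states) a full enumeration
takes on the order of a second; a hard cap at `n = 25` makes the
exponential cost an explicit opt-in rather than an accident.

## Synthetic data and what the tests show

Everything in the test suite runs on internally generated inputs: toy
motifs with hand-computable censuses, seeded random digraphs, and
pipeline outputs at reduced search budgets.  These exercise exactness
properties (oracle agreement for FFL/FBL enumeration, attractor detection
against trajectory following, optimizer results against full `2^|E|`
enumeration) and structural contracts, which transfer directly to real
inputs because they are input-independent.  What synthetic inputs cannot
show is whether the *shipped default* target vectors match any particular
empirical meta-analysis — that depends on user-supplied targets — nor how
close the stochastic searches get to their targets on budgets other than
those tested.  The published-attractor cross-validation additionally
requires the released dataset deposit on disk
(`data/zenodo_17406797/<kingdom>/`); its test states this requirement
explicitly and fails when the deposit is absent.

## Numerical and degenerate-input choices

* Distribution distance on a zero-mass vector is an error, not 0 or 1.
* A graph with no FFL clusters scores the maximal cluster error (1.0),
  steering the topology search toward cluster-bearing graphs.
* `sign_fit_error` on a graph with no FFLs (or no cycles) scores that
  component 0 — there is nothing to mismatch; the seeding stage instead
  warns and returns an empty partial signing.
* Score comparisons use a strict `<` with a 1e-12 slack so floating-point
  noise cannot masquerade as an improvement; exact-tie resolution is
  lexicographic.
* `M` exceeding the free-edge count is clamped with a warning; `M + L`
  over the cap is an error.

## Known limitations

* The topology search is greedy hill-climbing; it finds good, not
  provably optimal, distribution fits, and the deposited networks of the
  original release cannot be regenerated edge-for-edge (the searches are
  stochastic and their seeds unpublished).
* Scaling beyond a few hundred nodes (topology) or `n = 25` (dynamics) is
  out of scope by design.
* Only synchronous deterministic updates are implemented; asynchronous
  and probabilistic schemes are non-goals.
* Motif significance testing against randomised ensembles (Z-scores) and
  network image rendering are not provided.
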