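# grnbench

Benchmark Boolean network (BN) models of gene regulatory networks (GRNs),
built from the structural and dynamical regularities observed across real
GRN models rather than from any single hand-picked system.

Algorithms for BN analysis — attractor detection, control, reduction,
inference — are usually tested on ad hoc model collections, which can bias
evaluations toward whatever those models happen to contain.  `grnbench`
constructs *standardised* test networks that reproduce the recurrent
features of real GRN models: a scale-free out-degree distribution with an
approximately Poisson in-degree distribution, realistic frequencies of
feed-forward-loop (FFL) clusters, kingdom-specific distributions of signed
motifs (coherent/incoherent FFL types, positive/negative feedback loops,
activator fractions by in-degree), and fully canalizing update rules.  It
is aimed at researchers who need reproducible, unbiased inputs for testing
BN algorithms and theory.

## The model

A synchronous BN on a digraph `G = (V, E)` with `n = |V|` nodes is a map

    F = (F_1, ..., F_n) : {0,1}^n -> {0,1}^n

where `F_v` depends only on the regulators of `v` (its in-neighbours); a
configuration `a` with `F^m(a) = a` and `F^k(a) != a` for `0 < k < m` is an
attractor of length `m` (`m = 1`: fixed point).  Edges carry signs
`sigma(u,v) = +1` (activation) or `-1` (inhibition), and the sign of a path
is the product of its edge signs.  An FFL is the motif `u -> v -> w`,
`u -> w`; it is *coherent* when `sigma(u,w) = sigma(u,v) * sigma(v,w)`.
A feedback loop (FBL) is a simple directed cycle.

The pipeline has four stages:

1. **Topology** (`grnbench.topology`) — a 20-node simple digraph is fitted
   by seeded stochastic local search until it has 50 edges (average
   connectivity `<k> = |E|/n = 2.5`), exactly one external parameter (a
   node with no regulators), weak connectivity, out-degrees close to
   `P(k) ~ k^-gamma`, in-degrees close to Poisson, and an FFL-cluster
   spectrum close to its target.
2. **Signs** (`grnbench.signs`) — per kingdom (animal, bacteria, fungi,
   plant), edge signs minimise the weighted error (weights 1/3 each) over
   the FFL-type distribution, the fraction of positive FBLs by cycle
   length 1–6, and the activator fraction by in-degree, via seeded random
   assignment plus exhaustive search over `2^(M+L)` open edges.
3. **Rules** (`grnbench.rules`) — three families of fully canalizing,
   sign-consistent update functions per signed network: OR-NOT,
   AND-OR-NOT, and general nested canalizing.
4. **Dynamics** (`grnbench.dynamics`) — exact synchronous attractor
   enumeration over all `2^n` configurations, with basin sizes.

## Worked example

```python
import numpy as np
from grnbench import (GeneratorConfig, OptimizerConfig, default_targets,
                      generate_underlying, optimize_kingdom,
                      assemble_network, find_attractors, summarize)

cfg = GeneratorConfig(n=20, rng_seed=1)         # targets: <k>=2.5, 1 external
res = generate_underlying(cfg)
g = res.graph
print(g.n, g.n_edges, len(g.external_nodes()))  # -> 20 50 1

targets = default_targets()
opt = OptimizerConfig(n_candidates=3, n_iterations=5,
                      M_L_grid=((3, 2),), pool_size=200, rng_seed=7)
signed = optimize_kingdom(g, "bacteria", targets, opt)
print(round(signed.error.total, 3))             # -> 0.165 (weighted fit error)

bn = assemble_network(signed.signed, "GENERAL", rng=np.random.default_rng(3))
for kind, count in summarize(find_attractors(bn)):
    print(kind, count)
# 2-periodic 4
# 4-periodic 2
```

The first block fits the 20-node underlying topology: 50 directed edges
gives the target average connectivity of 2.5, and the single in-degree-0
node is the external parameter, held constant by the dynamics.  The sign
optimizer reports the residual weighted distance between the realised and
target sign-motif distributions (0 would be a perfect match; the small
search budget here is for illustration).  The final lines enumerate the
synchronous attractors of a general-canalizing model exactly: in this run,
four 2-cycles and two 4-cycles partition all 2^20 configurations into
basins.

The same pipeline is scriptable from the shell:

```sh
grnbench gen-topology --seed 1 --out-dir model
grnbench assign-signs --topology model/underlying.csv --kingdom fungi \
    --seed 1 --out model/fungi.csv
grnbench build-rules --signed model/fungi.csv --family OR_NOT --seed 1 \
    --out model/or_not.txt
grnbench attractors --signed model/fungi.csv --rules model/or_not.txt
grnbench validate --dir model
```

`grnbench config-dump` prints every tunable parameter and all kingdom
target vectors as YAML; pass an edited copy back with `--config`.

## File formats

Networks are exchanged as square adjacency CSVs (rows = regulator,
columns = target, entries in {-1, 0, +1}) and rules as "targets, factors"
text files (`node, expression` with `&`/`|`/`!` or `AND`/`OR`/`NOT`), so
models interoperate with the common BN toolchains.  See
`docs/methods.md` for the full methods description and design rationale.
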