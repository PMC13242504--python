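"""Construction of the unsigned underlying benchmark topology.

The underlying network is a small simple digraph (default n = 20) whose
structure matches summary statistics of real gene regulatory network
models: a power-law out-degree distribution, an approximately Poisson
in-degree distribution, the empirical distribution of feed-forward-loop
cluster motifs, a target average connectivity, and a fixed number of
external-parameter nodes (in-degree 0).

The fit is a seeded stochastic local search.  An initial graph is drawn
from the parametric degree targets, repaired to satisfy the hard
constraints (exact edge count, exact external-parameter count, weak
connectivity, every regulated node keeps at least one regulator), and then
improved by greedy hill-climbing over feasibility-preserving edge rewires:
a rewire is accepted iff it strictly lowers the weighted total score.
Several independent restarts are run and the best graph kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .graphs import DirectedGraph, distribution_distance, is_weakly_connected
from .motifs import enumerate_clusters
from .targets import N_CLUSTER_MOTIFS, TargetDistributions

__all__ = [
    "GeneratorConfig",
    "TopologyScore",
    "GenerationResult",
    "sample_initial_graph",
    "score_topology",
    "propose_modification",
    "generate_underlying",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the underlying-topology search.

    ``stage_weights`` weighs the five score components (out-degree,
    in-degree, FFL-cluster distribution, average connectivity, external
    count); equal weights by default.
    """

    n: int = 20
    targets: TargetDistributions = field(default_factory=TargetDistributions)
    max_iterations: int = 4000
    n_restarts: int = 2
    rng_seed: int = 0
    stage_weights: tuple[float, float, float, float, float] = (0.2,) * 5
    tolerance: float = 0.02
    edge_band: float = 0.10  # admissible |E| excursion around n * <k>

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        w = self.stage_weights
        if len(w) != 5 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("stage_weights must be 5 nonnegative values summing to 1")
        if self.targets.n_external >= self.n:
            raise ValueError("n_external must be smaller than n")

    @property
    def target_edges(self) -> int:
        return round(self.n * self.targets.mean_connectivity)


@dataclass(frozen=True)
class TopologyScore:
    out_deg_err: float
    in_deg_err: float
    cluster_err: float
    connectivity_err: float
    external_err: float
    total: float

    def components(self) -> tuple[float, ...]:
        return (self.out_deg_err, self.in_deg_err, self.cluster_err,
                self.connectivity_err, self.external_err)


@dataclass(frozen=True)
class GenerationResult:
    graph: DirectedGraph
    score: TopologyScore
    converged: bool
    n_accepted: int
    score_trace: tuple[float, ...]  # total after each accepted move


def power_law_pmf(gamma: float, k_min: int, k_max: int) -> dict[int, float]:
    """Discrete power law P(k) ~ k**-gamma on [k_min, k_max], normalised
    by explicit summation."""
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    ks = range(k_min, k_max + 1)
    w = {k: k ** -gamma for k in ks}
    z = sum(w.values())
    return {k: x / z for k, x in w.items()}


def truncated_poisson_pmf(rate: float, k_max: int) -> dict[int, float]:
    """Poisson pmf truncated to [0, k_max] and renormalised."""
    p = stats.poisson.pmf(np.arange(k_max + 1), rate)
    p = p / p.sum()
    return {k: float(p[k]) for k in range(k_max + 1)}


def _node_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def sample_initial_graph(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> DirectedGraph:
    """Draw a simple digraph from the parametric degree targets.

    Out-degrees are drawn from the truncated power law and each node's
    targets are chosen uniformly among the non-external nodes without
    duplicating edges.  The external nodes are a seeded random choice and
    never receive incoming edges; afterwards any other node that happens
    to have in-degree 0 is given one random regulator, so the graph has
    exactly ``n_external`` external parameters.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    t = cfg.targets
    n = cfg.n
    labels = _node_labels(n)
    capacity = n - t.n_external  # legal targets per source (incl. self-loop)
    if capacity < 1:
        raise ValueError("no legal edge targets: n_external too large")
    pmf = power_law_pmf(t.gamma, max(1, t.k_out_min), n - 1)
    ks = np.array(sorted(pmf))
    ps = np.array([pmf[k] for k in ks])

    external = set(rng.choice(labels, size=t.n_external, replace=False)) \
        if t.n_external else set()
    internal = [v for v in labels if v not in external]

    g = DirectedGraph(labels)
    for u in labels:
        k = int(rng.choice(ks, p=ps))
        k = min(k, capacity if u in internal else len(internal))
        pool = [v for v in internal if v != u] if u in external else internal
        for v in rng.choice(pool, size=min(k, len(pool)), replace=False):
            g.add_edge(u, str(v))
    # absorb accidental in-degree-0 nodes so external count is exact
    for v in internal:
        if g.in_degree(v) == 0:
            candidates = [u for u in labels if not g.has_edge(u, v)]
            g.add_edge(str(rng.choice(candidates)), v)
    return g


def _hist_from_degrees(degrees: Sequence[int]) -> dict[int, int]:
    h: dict[int, int] = {}
    for k in degrees:
        h[k] = h.get(k, 0) + 1
    return h


def score_topology(g: DirectedGraph, cfg: GeneratorConfig) -> TopologyScore:
    """Weighted distance between the graph's statistics and the targets.

    Distribution components are total-variation distances in [0, 1]; the
    connectivity component is ``|<k> - target|`` and the external
    component the absolute count error.  The total is zero iff every
    component is zero.
    """
    t = cfg.targets
    out_hist = _hist_from_degrees([g.out_degree(v) for v in g.nodes])
    in_hist = _hist_from_degrees([g.in_degree(v) for v in g.nodes])
    out_target = power_law_pmf(t.gamma, max(1, t.k_out_min), g.n - 1)
    in_target = truncated_poisson_pmf(t.poisson_rate, g.n - 1)
    out_err = distribution_distance(out_hist, out_target)
    in_err = distribution_distance(in_hist, in_target)

    clusters = enumerate_clusters(g)
    observed = {i: clusters.get(i, 0) for i in range(1, N_CLUSTER_MOTIFS + 1)}
    if sum(observed.values()) == 0:
        cluster_err = 1.0  # no clusters at all: maximal mismatch
    else:
        cluster_err = distribution_distance(
            observed, dict(enumerate(t.ffl_cluster_freq, start=1))
        )

    conn_err = abs(g.n_edges / g.n - t.mean_connectivity)
    ext_err = float(abs(len(g.external_nodes()) - t.n_external))
    w = cfg.stage_weights
    comps = (out_err, in_err, cluster_err, conn_err, ext_err)
    return TopologyScore(*comps, total=float(sum(wi * c for wi, c in zip(w, comps))))


_MOVE_KINDS = ("add", "delete", "rewire")


def propose_modification(
    g: DirectedGraph,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    kinds: Sequence[str] = _MOVE_KINDS,
) -> tuple[DirectedGraph, bool]:
    """One random legal edge move (add / delete / rewire).

    The candidate stays a simple digraph, external-parameter nodes never
    gain incoming edges, regulated nodes never lose their last regulator,
    and the edge count stays within ``edge_band`` of ``n * <k>``.  Returns
    ``(candidate, moved)``; ``moved`` is False when no legal move of the
    drawn kind exists (the graph is returned unchanged).
    """
    target_e = cfg.n * cfg.targets.mean_connectivity
    lo = math.floor(target_e * (1 - cfg.edge_band))
    hi = math.ceil(target_e * (1 + cfg.edge_band))
    external = set(g.external_nodes())
    legal_targets = [v for v in g.nodes if v not in external]

    kind = str(rng.choice(list(kinds)))
    cand = g.copy()
    if kind == "add":
        if g.n_edges >= hi:
            return g, False
        options = [
            (u, v) for u in g.nodes for v in legal_targets if not g.has_edge(u, v)
        ]
        if not options:
            return g, False
        u, v = options[rng.integers(len(options))]
        cand.add_edge(u, v)
        return cand, True
    if kind == "delete":
        if g.n_edges <= lo:
            return g, False
        options = [e for e in g.sorted_edges() if g.in_degree(e[1]) > 1]
        if not options:
            return g, False
        u, v = options[rng.integers(len(options))]
        cand.remove_edge(u, v)
        return cand, True
    # rewire: move one endpoint of a random edge
    edges = g.sorted_edges()
    if not edges:
        return g, False
    for _ in range(20):  # retry a few times; rewires can be locally blocked
        u, v = edges[rng.integers(len(edges))]
        if rng.integers(2) == 0:  # move target
            opts = [w for w in legal_targets if w != v and not g.has_edge(u, w)]
            if not opts or g.in_degree(v) <= 1:
                continue
            w = opts[rng.integers(len(opts))]
            cand = g.copy()
            cand.remove_edge(u, v)
            cand.add_edge(u, w)
            return cand, True
        else:  # move source
            opts = [w for w in g.nodes if w != u and not g.has_edge(w, v)]
            if not opts:
                continue
            w = opts[rng.integers(len(opts))]
            cand = g.copy()
            cand.remove_edge(u, v)
            cand.add_edge(w, v)
            return cand, True
    return g, False


def _repair(g: DirectedGraph, cfg: GeneratorConfig, rng: np.random.Generator) -> None:
    """Bring the graph to the feasible set in place: exact edge count,
    exact external count, weak connectivity."""
    external = set(g.external_nodes())
    legal_targets = [v for v in g.nodes if v not in external]
    target_e = cfg.target_edges

    for _ in range(10 * cfg.n + 100):
        if g.n_edges < target_e:
            options = [
                (u, v) for u in g.nodes for v in legal_targets if not g.has_edge(u, v)
            ]
            u, v = options[rng.integers(len(options))]
            g.add_edge(u, v)
        elif g.n_edges > target_e:
            options = [
                e for e in g.sorted_edges()
                if g.in_degree(e[1]) > 1 and _removal_keeps_connected(g, e)
            ]
            if not options:
                options = [e for e in g.sorted_edges() if g.in_degree(e[1]) > 1]
            u, v = options[rng.integers(len(options))]
            g.remove_edge(u, v)
        elif not is_weakly_connected(g):
            _connect_components(g, rng, legal_targets)
        else:
            return
    raise RuntimeError("repair failed to reach a feasible graph")


def _removal_keeps_connected(g: DirectedGraph, e: tuple[str, str]) -> bool:
    g.remove_edge(*e)
    ok = is_weakly_connected(g)
    g.add_edge(*e)
    return ok


def _connect_components(
    g: DirectedGraph, rng: np.random.Generator, legal_targets: list[str]
) -> None:
    """Merge two weak components by rewiring an intra-component edge
    (keeps the edge count unchanged)."""
    import networkx as nx

    comps = [sorted(c) for c in nx.weakly_connected_components(g.to_networkx())]
    comps.sort(key=len, reverse=True)
    big, small = set(comps[0]), comps[-1]
    # delete a redundant edge inside the big component, add a bridge
    options = [
        e for e in g.sorted_edges()
        if e[0] in big and e[1] in big and g.in_degree(e[1]) > 1
    ]
    if not options:
        raise RuntimeError("cannot rewire for connectivity")
    g.remove_edge(*options[rng.integers(len(options))])
    u = small[rng.integers(len(small))]
    opts = [v for v in legal_targets if v in big and not g.has_edge(u, v)]
    if opts:
        g.add_edge(u, opts[rng.integers(len(opts))])
    else:
        src = sorted(big)[rng.integers(len(big))]
        tgt = [v for v in small if v in legal_targets and not g.has_edge(src, v)]
        g.add_edge(src, tgt[rng.integers(len(tgt))])


def _feasible(g: DirectedGraph, cfg: GeneratorConfig) -> bool:
    return (
        g.n_edges == cfg.target_edges
        and len(g.external_nodes()) == cfg.targets.n_external
        and is_weakly_connected(g)
    )


def generate_underlying(cfg: GeneratorConfig) -> GenerationResult:
    """Fit the underlying topology to the target statistics.

    Greedy hill-climbing with restarts over feasibility-preserving rewires;
    a move is accepted iff it strictly lowers the total score, so the
    accepted-score trace is strictly decreasing.  The returned graph always
    satisfies the hard constraints (edge count ``round(n * <k>)``, exactly
    ``n_external`` in-degree-0 nodes, weak connectivity); ``converged``
    reports whether the soft distribution score reached the tolerance
    within the iteration budget.
    """
    best: GenerationResult | None = None
    for restart in range(cfg.n_restarts):
        rng = np.random.default_rng((cfg.rng_seed, restart))
        g = sample_initial_graph(cfg, rng)
        _repair(g, cfg, rng)
        score = score_topology(g, cfg)
        trace = [score.total]
        accepted = 0
        for _ in range(cfg.max_iterations):
            if score.total <= cfg.tolerance:
                break
            cand, moved = propose_modification(g, rng, cfg, kinds=("rewire",))
            if not moved or not _feasible(cand, cfg):
                continue
            cand_score = score_topology(cand, cfg)
            if cand_score.total < score.total - 1e-12:
                g, score = cand, cand_score
                trace.append(score.total)
                accepted += 1
        result = GenerationResult(
            graph=g,
            score=score,
            converged=score.total <= cfg.tolerance,
            n_accepted=accepted,
            score_trace=tuple(trace),
        )
        if best is None or result.score.total < best.score.total:
            best = result
        if best.converged:
            break
    assert best is not None
    return best
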