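"""Synchronous state-space analysis of Boolean networks.

Configurations are packed as integers: bit ``i`` (least significant = node
0 in the network's node order) holds the state of node ``i``.  The global
map ``F`` updates all nodes simultaneously; external parameters copy their
own state and therefore split the state space into invariant slices.

Attractor enumeration is exhaustive and exact: the successor of every one
of the ``2**n`` configurations is computed (vectorised), the functional
graph is peeled down to its cycles, and each cycle is reported with its
minimal period and basin size.  A hard cap on ``n`` protects against
accidental exponential blow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rules import BooleanNetwork

__all__ = [
    "step",
    "transition_table",
    "Attractor",
    "AttractorSummary",
    "find_attractors",
    "summarize",
]

HARD_CAP = 25  # 2**25 successor evaluations; beyond this, refuse


def step(bn: BooleanNetwork, x: int) -> int:
    """Apply the global map to one packed configuration."""
    nodes = bn.nodes
    index = {v: i for i, v in enumerate(nodes)}
    y = 0
    for i, v in enumerate(nodes):
        if v in bn.external:
            bit = (x >> i) & 1
        else:
            f = bn.functions[v]
            idx = 0
            for j, u in enumerate(f.inputs):
                idx |= ((x >> index[u]) & 1) << j
            bit = f.table[idx]
        y |= bit << i
    return y


def transition_table(bn: BooleanNetwork) -> np.ndarray:
    """Successor of every configuration 0 .. 2**n - 1 (vectorised)."""
    n = bn.n
    if n > HARD_CAP:
        raise ValueError(
            f"n = {n} exceeds the exhaustive-enumeration cap ({HARD_CAP}); "
            "analyse a subnetwork or raise the cap deliberately"
        )
    index = {v: i for i, v in enumerate(bn.nodes)}
    states = np.arange(1 << n, dtype=np.int64)
    succ = np.zeros_like(states)
    for i, v in enumerate(bn.nodes):
        if v in bn.external:
            bit = (states >> i) & 1
        else:
            f = bn.functions[v]
            idx = np.zeros_like(states)
            for j, u in enumerate(f.inputs):
                idx |= ((states >> index[u]) & 1) << j
            bit = np.asarray(f.table, dtype=np.int64)[idx]
        succ |= bit << i
    return succ


@dataclass(frozen=True)
class Attractor:
    """Minimal-period cycle, canonicalised to start at its smallest state."""

    states: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return self.length == 1

    @property
    def kind(self) -> str:
        return "fixed point" if self.is_fixed_point else f"{self.length}-periodic"


@dataclass(frozen=True)
class AttractorSummary:
    n: int
    attractors: tuple[Attractor, ...]
    basin_sizes: tuple[int, ...]  # aligned with attractors

    @property
    def counts(self) -> dict[int, int]:
        """Number of attractors per length."""
        c: dict[int, int] = {}
        for a in self.attractors:
            c[a.length] = c.get(a.length, 0) + 1
        return dict(sorted(c.items()))

    def basin_of(self, a: Attractor) -> int:
        return self.basin_sizes[self.attractors.index(a)]


def find_attractors(bn: BooleanNetwork) -> AttractorSummary:
    """Exhaustively enumerate all attractors and their basins.

    The functional graph of the global map decomposes into rho-shaped
    components; non-cycle states are peeled off in topological order and
    the remaining states form the attractor cycles.  Every configuration
    reaches exactly one attractor, so basin sizes sum to ``2**n``.
    """
    succ = transition_table(bn)
    n_states = len(succ)
    indeg = np.bincount(succ, minlength=n_states)
    order: list[int] = []
    stack = list(np.flatnonzero(indeg == 0))
    while stack:
        x = int(stack.pop())
        order.append(x)
        y = int(succ[x])
        indeg[y] -= 1
        if indeg[y] == 0:
            stack.append(y)
    on_cycle = indeg > 0

    attractors: list[Attractor] = []
    attr_id = np.full(n_states, -1, dtype=np.int64)
    for s in np.flatnonzero(on_cycle):
        s = int(s)
        if attr_id[s] >= 0:
            continue
        cyc = [s]
        x = int(succ[s])
        while x != s:
            cyc.append(x)
            x = int(succ[x])
        k = np.argmin(cyc)
        cyc = cyc[k:] + cyc[:k]
        aid = len(attractors)
        attractors.append(Attractor(tuple(cyc)))
        for y in cyc:
            attr_id[y] = aid
    for x in reversed(order):
        attr_id[x] = attr_id[succ[x]]

    basins = np.bincount(attr_id, minlength=len(attractors))
    # stable reporting order: by length, then smallest contained state
    idx = sorted(range(len(attractors)),
                 key=lambda i: (attractors[i].length, attractors[i].states[0]))
    return AttractorSummary(
        n=bn.n,
        attractors=tuple(attractors[i] for i in idx),
        basin_sizes=tuple(int(basins[i]) for i in idx),
    )


def summarize(summary: AttractorSummary) -> list[tuple[str, int]]:
    """Table rows ``(type, number)`` sorted by attractor length; lengths
    with no attractors are omitted."""
    rows = []
    for length, count in summary.counts.items():
        label = "fixed point" if length == 1 else f"{length}-periodic"
        rows.append((label, count))
    return rows
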