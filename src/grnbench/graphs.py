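"""Core graph data model for gene regulatory network benchmarks.

A regulatory network is a simple directed graph: nodes are genes (or an
external parameter), a directed edge ``u -> v`` means *u regulates v*.
Self-loops are permitted (a gene may regulate itself); parallel edges are
not.  A :class:`SignedGraph` adds an activating/inhibiting sign per edge,
possibly partial while sign assignment is in progress.

Degree conventions follow the field: the in-degree of a node is its number
of regulators, the out-degree its number of targets, and the average
connectivity ``<k>`` is the mean in-degree, equal to ``|E| / n``.  A node
with no regulators is an *external parameter*: it is held constant by the
dynamics and carries no update function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

Edge = tuple[str, str]

__all__ = [
    "DirectedGraph",
    "SignedGraph",
    "DegreeReport",
    "degree_report",
    "distribution_distance",
    "is_weakly_connected",
]


class DirectedGraph:
    """Simple directed graph with ordered, opaque string node labels.

    Duplicate edges are rejected; self-loops are allowed.  Mutation is
    restricted to :meth:`add_edge` / :meth:`remove_edge` so successor and
    predecessor indices stay consistent.
    """

    __slots__ = ("nodes", "_succ", "_pred", "_n_edges")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge] = ()):
        self.nodes: tuple[str, ...] = tuple(str(x) for x in nodes)
        if len(self.nodes) < 1:
            raise ValueError("a graph needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        self._succ: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._pred: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._n_edges = 0
        for u, v in edges:
            self.add_edge(u, v)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    @property
    def edges(self) -> set[Edge]:
        return {(u, v) for u, ts in self._succ.items() for v in ts}

    def sorted_edges(self) -> list[Edge]:
        """Edges in node order (stable across runs; used for sign vectors)."""
        order = {v: i for i, v in enumerate(self.nodes)}
        return sorted(self.edges, key=lambda e: (order[e[0]], order[e[1]]))

    def has_node(self, v: str) -> bool:
        return v in self._succ

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._succ and v in self._succ[u]

    def successors(self, u: str) -> frozenset[str]:
        return frozenset(self._succ[u])

    def predecessors(self, v: str) -> frozenset[str]:
        return frozenset(self._pred[v])

    def out_degree(self, u: str) -> int:
        return len(self._succ[u])

    def in_degree(self, v: str) -> int:
        return len(self._pred[v])

    def external_nodes(self) -> list[str]:
        """Nodes with no regulators, i.e. external parameters."""
        return [v for v in self.nodes if not self._pred[v]]

    # -- mutation --------------------------------------------------------
    def add_edge(self, u: str, v: str) -> None:
        if u not in self._succ or v not in self._succ:
            raise KeyError(f"edge endpoint not declared: ({u!r}, {v!r})")
        if v in self._succ[u]:
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        self._succ[u].add(v)
        self._pred[v].add(u)
        self._n_edges += 1

    def remove_edge(self, u: str, v: str) -> None:
        if u not in self._succ or v not in self._succ[u]:
            raise KeyError(f"no such edge ({u!r}, {v!r})")
        self._succ[u].discard(v)
        self._pred[v].discard(u)
        self._n_edges -= 1

    # -- conversion / copying -------------------------------------------
    def copy(self) -> "DirectedGraph":
        g = DirectedGraph(self.nodes)
        for u, ts in self._succ.items():
            for v in ts:
                g._succ[u].add(v)
                g._pred[v].add(u)
        g._n_edges = self._n_edges
        return g

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedGraph":
        return cls([str(v) for v in g.nodes], [(str(u), str(v)) for u, v in g.edges])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"DirectedGraph(n={self.n}, edges={self.n_edges})"


@dataclass
class SignedGraph:
    """A directed graph plus an edge sign map ``sigma`` in {+1, -1}.

    The sign map may be partial while sign assignment is running; a
    totally signed graph has a sign for every edge.
    """

    graph: DirectedGraph
    signs: dict[Edge, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e, s in self.signs.items():
            if not self.graph.has_edge(*e):
                raise ValueError(f"sign assigned to non-edge {e}")
            if s not in (+1, -1):
                raise ValueError(f"illegal sign {s!r} on edge {e}")

    @property
    def is_total(self) -> bool:
        return len(self.signs) == self.graph.n_edges

    def sign(self, u: str, v: str) -> int:
        try:
            return self.signs[(u, v)]
        except KeyError:
            raise KeyError(f"edge ({u!r}, {v!r}) is unsigned or absent") from None

    def with_signs(self, more: Mapping[Edge, int]) -> "SignedGraph":
        merged = dict(self.signs)
        merged.update(more)
        return SignedGraph(self.graph, merged)

    def copy(self) -> "SignedGraph":
        return SignedGraph(self.graph.copy(), dict(self.signs))


@dataclass(frozen=True)
class DegreeReport:
    out_degree_hist: dict[int, int]
    in_degree_hist: dict[int, int]
    mean_connectivity: float
    external_nodes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "out_degree_hist": dict(self.out_degree_hist),
            "in_degree_hist": dict(self.in_degree_hist),
            "mean_connectivity": self.mean_connectivity,
            "external_nodes": list(self.external_nodes),
        }


def degree_report(g: DirectedGraph) -> DegreeReport:
    """Degree histograms, average connectivity and external parameters."""
    out_hist: dict[int, int] = {}
    in_hist: dict[int, int] = {}
    for v in g.nodes:
        ko, ki = g.out_degree(v), g.in_degree(v)
        out_hist[ko] = out_hist.get(ko, 0) + 1
        in_hist[ki] = in_hist.get(ki, 0) + 1
    return DegreeReport(
        out_degree_hist=out_hist,
        in_degree_hist=in_hist,
        mean_connectivity=g.n_edges / g.n,
        external_nodes=tuple(g.external_nodes()),
    )


def _as_freq_map(vec) -> dict:
    if isinstance(vec, Mapping):
        return {k: float(w) for k, w in vec.items()}
    if isinstance(vec, Sequence):
        return {i: float(w) for i, w in enumerate(vec)}
    raise TypeError(f"not a frequency vector: {type(vec).__name__}")


def distribution_distance(observed, target) -> float:
    """Total-variation (half L1) distance between two frequency vectors.

    Inputs are mappings ``bin -> weight`` or sequences (bin = index).  Each
    is normalised to sum 1 over the union of supports, so zero-padding the
    support does not change the result.  The distance lies in [0, 1] and is
    0 iff the normalised vectors are identical.
    """
    if (
        isinstance(observed, Sequence)
        and isinstance(target, Sequence)
        and len(observed) != len(target)
    ):
        raise ValueError(
            f"mismatched support: {len(observed)} vs {len(target)} bins"
        )
    p, q = _as_freq_map(observed), _as_freq_map(target)
    for name, m in (("observed", p), ("target", q)):
        if any(w < 0 for w in m.values()):
            raise ValueError(f"{name} vector has negative weight")
        tot = sum(m.values())
        if tot <= 0:
            raise ValueError(f"{name} vector sums to zero")
        for k in m:
            m[k] /= tot
    support = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in support)


def is_weakly_connected(g: DirectedGraph) -> bool:
    """True iff the underlying undirected graph has a single component."""
    return nx.is_weakly_connected(g.to_networkx())
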