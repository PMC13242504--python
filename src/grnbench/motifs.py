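"""Feed-forward loop, FFL-cluster and feedback-loop census.

A feed-forward loop (FFL) on nodes ``(u, v, w)`` is the ordered motif with
edges ``u->v``, ``v->w`` and ``u->w``: the regulator ``u`` acts on ``w``
both directly and through the mediator ``v``.  With signs, the FFL is
*coherent* when the direct edge carries the same sign as the two-step path
(``sigma(u,w) == sigma(u,v) * sigma(v,w)``) and *incoherent* otherwise;
the 2^3 sign assignments split into 4 coherent and 4 incoherent types.

Type numbering (the field has no universal convention, so this package
fixes one and uses it consistently for targets and reports): sort the sign
triples ``(sigma(u,v), sigma(v,w), sigma(u,w))`` lexicographically with
``+`` before ``-``; coherent triples get ids 1-4, incoherent 5-8.  Type 1
is therefore the all-activating coherent FFL.

FFLs that overlap form *clusters*.  Two FFLs sharing exactly one node fall
into 6 isomorphism classes of their union graph (motifs 1-6: the shared
node plays role u/v/w in either FFL); two FFLs sharing an edge (and hence
its two endpoints) into 6 more (motifs 7-12); a 3-node set carrying
exactly two FFLs gives motifs 13-14 and exactly three FFLs motif 15.
Overlaps outside this taxonomy (two shared nodes without a shared edge,
which requires a 2-cycle between them, or a complete 3-node digraph with
six FFLs) are tallied under key 0.

A feedback loop (FBL) is a simple directed cycle; length 1 is a self-loop.
Its sign is the product of its edge signs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

from .graphs import DegreeReport, DirectedGraph, SignedGraph, degree_report
from .targets import MAX_FBL_LEN, N_CLUSTER_MOTIFS, N_FFL_TYPES

__all__ = [
    "FFL",
    "FFLType",
    "FBL",
    "enumerate_ffls",
    "classify_ffl",
    "ffl_type_counts",
    "enumerate_clusters",
    "enumerate_fbls",
    "path_sign",
    "fbl_sign",
    "positive_fbl_fraction",
    "positive_input_fraction",
    "census_report",
    "CensusReport",
    "FFL_TYPE_BY_SIGNS",
]


class FFL(NamedTuple):
    """Ordered feed-forward loop: u regulates v and w, v regulates w."""

    u: str
    v: str
    w: str

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self)

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(((self.u, self.v), (self.v, self.w), (self.u, self.w)))


@dataclass(frozen=True)
class FFLType:
    type_id: int
    coherent: bool

    def __post_init__(self) -> None:
        if not 1 <= self.type_id <= N_FFL_TYPES:
            raise ValueError(f"type_id out of range: {self.type_id}")
        if self.coherent != (self.type_id <= 4):
            raise ValueError("type ids 1-4 are coherent, 5-8 incoherent")


def _build_type_table() -> dict[tuple[int, int, int], FFLType]:
    triples = list(itertools.product((+1, -1), repeat=3))
    lex = sorted(triples, key=lambda t: tuple(0 if s == +1 else 1 for s in t))
    coh = [t for t in lex if t[2] == t[0] * t[1]]
    inc = [t for t in lex if t[2] != t[0] * t[1]]
    table = {}
    for i, t in enumerate(coh, start=1):
        table[t] = FFLType(i, True)
    for i, t in enumerate(inc, start=5):
        table[t] = FFLType(i, False)
    return table


#: sign triple (sigma(u,v), sigma(v,w), sigma(u,w)) -> FFLType
FFL_TYPE_BY_SIGNS: dict[tuple[int, int, int], FFLType] = _build_type_table()


def enumerate_ffls(g: DirectedGraph) -> list[FFL]:
    """All ordered triples (u, v, w) with edges u->v, v->w, u->w.

    Self-loops never participate (the three nodes are distinct).
    """
    out = []
    for u in g.nodes:
        su = g.successors(u)
        for v in su:
            if v == u:
                continue
            for w in g.successors(v) & su:
                if w != u and w != v:
                    out.append(FFL(u, v, w))
    return sorted(out)


def classify_ffl(sg: SignedGraph, f: FFL) -> FFLType:
    """Signed type (1-8) of an FFL; raises if any of its edges is unsigned."""
    triple = (sg.sign(f.u, f.v), sg.sign(f.v, f.w), sg.sign(f.u, f.w))
    return FFL_TYPE_BY_SIGNS[triple]


def ffl_type_counts(sg: SignedGraph, ffls: Iterable[FFL] | None = None) -> dict[int, int]:
    """Count of FFLs per signed type id 1-8."""
    if ffls is None:
        ffls = enumerate_ffls(sg.graph)
    counts = {i: 0 for i in range(1, N_FFL_TYPES + 1)}
    for f in ffls:
        counts[classify_ffl(sg, f).type_id] += 1
    return counts


# ---------------------------------------------------------------------------
# FFL clusters
# ---------------------------------------------------------------------------

def _canonical_form(edges: Iterable[tuple], nodes: Iterable) -> tuple:
    """Adjacency-matrix canonical form: the lexicographically smallest
    flattened 0/1 matrix over all node permutations.  Brute force; cluster
    union graphs have at most 5 nodes."""
    nodes = sorted(set(nodes), key=str)
    idx = {x: i for i, x in enumerate(nodes)}
    n = len(nodes)
    e = [(idx[u], idx[v]) for u, v in edges]
    best = None
    for p in itertools.permutations(range(n)):
        m = [0] * (n * n)
        for u, v in e:
            m[p[u] * n + p[v]] = 1
        t = tuple(m)
        if best is None or t < best:
            best = t
    return best


def _abstract_pair_forms() -> dict[tuple, int]:
    """Map union-graph canonical form -> motif id, built by enumerating the
    abstract role configurations of overlapping FFL pairs."""
    registry: dict[tuple, int] = {}

    def union_form(f1: FFL, f2: FFL) -> tuple:
        edges = f1.edge_set | f2.edge_set
        nodes = f1.node_set | f2.node_set
        return _canonical_form(edges, nodes)

    # motifs 1-6: shared node in role r1 of FFL1 and r2 of FFL2
    forms1 = set()
    for r1 in range(3):
        for r2 in range(3):
            a = ["a0", "a1", "a2"]
            b = ["b0", "b1", "b2"]
            a[r1] = b[r2] = "s"
            forms1.add(union_form(FFL(*a), FFL(*b)))
    assert len(forms1) == 6
    for i, form in enumerate(sorted(forms1), start=1):
        registry[form] = i

    # motifs 7-12: the two FFLs share one edge (hence two nodes)
    forms2 = set()
    f1 = FFL("a", "b", "c")
    for shared in f1.edge_set:
        for perm in itertools.permutations((*shared, "z")):
            f2 = FFL(*perm)
            if shared in f2.edge_set and f2 != f1:
                forms2.add(union_form(f1, f2))
    assert len(forms2) == 6
    for i, form in enumerate(sorted(forms2), start=7):
        registry[form] = i

    # motifs 13-14: two distinct FFLs on one 3-node set
    forms3 = set()
    for perm in itertools.permutations(("a", "b", "c")):
        f2 = FFL(*perm)
        if f2 != f1:
            u = f1.edge_set | f2.edge_set
            if len(u) == 4:  # larger unions realise three or six FFLs
                forms3.add(union_form(f1, f2))
    assert len(forms3) == 2
    for i, form in enumerate(sorted(forms3), start=13):
        registry[form] = i

    return registry


_PAIR_FORMS = _abstract_pair_forms()


def enumerate_clusters(g: DirectedGraph, ffls: Sequence[FFL] | None = None) -> dict[int, int]:
    """Count FFL-cluster occurrences per motif id.

    Returns a map with keys 1-15 and key 0 for overlaps outside the
    taxonomy.  Pairs of FFLs sharing one node or an edge are counted per
    unordered pair (motifs 1-12).  Clusters confined to a single 3-node
    set are counted once per node set: exactly two FFLs give motif 13 or
    14, exactly three give motif 15; the complete 3-node digraph (six
    FFLs) falls under key 0.
    """
    if ffls is None:
        ffls = enumerate_ffls(g)
    counts = {i: 0 for i in range(0, N_CLUSTER_MOTIFS + 1)}

    by_node_set: dict[frozenset[str], list[FFL]] = {}
    for f in ffls:
        by_node_set.setdefault(f.node_set, []).append(f)

    for f1, f2 in itertools.combinations(ffls, 2):
        shared = f1.node_set & f2.node_set
        if len(shared) == 3:
            continue  # handled per 3-node set below
        if not shared:
            continue
        if len(shared) == 1:
            form = _canonical_form(f1.edge_set | f2.edge_set, f1.node_set | f2.node_set)
            counts[_PAIR_FORMS[form]] += 1
        elif f1.edge_set & f2.edge_set:
            form = _canonical_form(f1.edge_set | f2.edge_set, f1.node_set | f2.node_set)
            counts[_PAIR_FORMS[form]] += 1
        else:
            counts[0] += 1  # two shared nodes joined by a 2-cycle, no shared edge

    for members in by_node_set.values():
        if len(members) == 2:
            f1, f2 = members
            form = _canonical_form(f1.edge_set | f2.edge_set, f1.node_set)
            counts[_PAIR_FORMS[form]] += 1
        elif len(members) == 3:
            counts[15] += 1
        elif len(members) > 3:
            counts[0] += 1
    return counts


# ---------------------------------------------------------------------------
# Feedback loops
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FBL:
    """Simple directed cycle, rotation-normalised to start at its smallest
    node label; ``length == len(nodes)`` and length 1 is a self-loop."""

    nodes: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[str, str]]:
        ns = self.nodes
        return [(ns[i], ns[(i + 1) % len(ns)]) for i in range(len(ns))]


def _canonical_cycle(nodes: Sequence[str]) -> tuple[str, ...]:
    i = min(range(len(nodes)), key=lambda j: nodes[j])
    return tuple(nodes[i:]) + tuple(nodes[:i])


def enumerate_fbls(g: DirectedGraph, max_len: int = MAX_FBL_LEN) -> list[FBL]:
    """All simple directed cycles of length 1..max_len, each reported once."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    cycles = nx.simple_cycles(g.to_networkx(), length_bound=max_len)
    return sorted(
        (FBL(_canonical_cycle(c)) for c in cycles),
        key=lambda f: (f.length, f.nodes),
    )


def path_sign(sg: SignedGraph, path: Sequence[str]) -> int:
    """Product of edge signs along a node sequence; raises on a missing
    edge or sign."""
    if len(path) < 2:
        raise ValueError("a path needs at least one edge")
    s = 1
    for u, v in zip(path, path[1:]):
        s *= sg.sign(u, v)
    return s


def fbl_sign(sg: SignedGraph, f: FBL) -> int:
    s = 1
    for u, v in f.edges():
        s *= sg.sign(u, v)
    return s


def positive_fbl_fraction(
    sg: SignedGraph, max_len: int = MAX_FBL_LEN, fbls: Sequence[FBL] | None = None
) -> dict[int, float | None]:
    """Fraction of positive FBLs per length 1..max_len; None for lengths
    with no cycles."""
    if fbls is None:
        fbls = enumerate_fbls(sg.graph, max_len)
    pos = {m: 0 for m in range(1, max_len + 1)}
    tot = {m: 0 for m in range(1, max_len + 1)}
    for f in fbls:
        if f.length > max_len:
            continue
        tot[f.length] += 1
        if fbl_sign(sg, f) == +1:
            pos[f.length] += 1
    return {
        m: (pos[m] / tot[m] if tot[m] else None) for m in range(1, max_len + 1)
    }


def positive_input_fraction(sg: SignedGraph) -> dict[int, float]:
    """Fraction of activating (positive) incoming edges, grouped by the
    target node's in-degree; only occupied in-degrees >= 1 appear."""
    pos: dict[int, int] = {}
    tot: dict[int, int] = {}
    g = sg.graph
    for v in g.nodes:
        k = g.in_degree(v)
        if k == 0:
            continue
        for u in g.predecessors(v):
            tot[k] = tot.get(k, 0) + 1
            if sg.sign(u, v) == +1:
                pos[k] = pos.get(k, 0) + 1
    return {k: pos.get(k, 0) / tot[k] for k in sorted(tot)}


# ---------------------------------------------------------------------------
# Full census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusReport:
    """Validation statistics of one (totally signed) benchmark network."""

    kingdom: str | None
    ffl_type_counts: dict[int, int]
    cluster_counts: dict[int, int]
    fbl_positive_fraction: dict[int, float | None]
    pos_input_fraction: dict[int, float]
    degrees: DegreeReport
    n_ffls: int
    n_fbls: int

    def ffl_type_freq(self) -> tuple[float, ...]:
        tot = sum(self.ffl_type_counts.values())
        if tot == 0:
            raise ValueError("no FFLs: type frequency undefined")
        return tuple(self.ffl_type_counts[i] / tot for i in range(1, N_FFL_TYPES + 1))

    def to_dict(self) -> dict:
        return {
            "kingdom": self.kingdom,
            "ffl_type_counts": dict(self.ffl_type_counts),
            "cluster_counts": dict(self.cluster_counts),
            "fbl_positive_fraction": dict(self.fbl_positive_fraction),
            "pos_input_fraction": dict(self.pos_input_fraction),
            "degrees": self.degrees.to_dict(),
            "n_ffls": self.n_ffls,
            "n_fbls": self.n_fbls,
        }

    def to_rows(self) -> list[dict]:
        """Flat tabular form: one row per statistic bin."""
        rows = []
        for i in range(1, N_FFL_TYPES + 1):
            rows.append({"statistic": "ffl_type", "bin": i,
                         "value": self.ffl_type_counts[i]})
        for i in range(0, N_CLUSTER_MOTIFS + 1):
            rows.append({"statistic": "cluster_motif", "bin": i,
                         "value": self.cluster_counts.get(i, 0)})
        for m, frac in self.fbl_positive_fraction.items():
            rows.append({"statistic": "fbl_positive_fraction", "bin": m,
                         "value": frac})
        for k, frac in self.pos_input_fraction.items():
            rows.append({"statistic": "pos_input_fraction", "bin": k,
                         "value": frac})
        for k, c in sorted(self.degrees.out_degree_hist.items()):
            rows.append({"statistic": "out_degree_hist", "bin": k, "value": c})
        for k, c in sorted(self.degrees.in_degree_hist.items()):
            rows.append({"statistic": "in_degree_hist", "bin": k, "value": c})
        rows.append({"statistic": "mean_connectivity", "bin": None,
                     "value": self.degrees.mean_connectivity})
        return rows


def census_report(sg: SignedGraph, kingdom: str | None = None) -> CensusReport:
    """All motif/degree validation statistics for a totally signed network."""
    if not sg.is_total:
        raise ValueError("census requires a totally signed graph")
    ffls = enumerate_ffls(sg.graph)
    fbls = enumerate_fbls(sg.graph)
    return CensusReport(
        kingdom=kingdom,
        ffl_type_counts=ffl_type_counts(sg, ffls),
        cluster_counts=enumerate_clusters(sg.graph, ffls),
        fbl_positive_fraction=positive_fbl_fraction(sg, fbls=fbls),
        pos_input_fraction=positive_input_fraction(sg),
        degrees=degree_report(sg.graph),
        n_ffls=len(ffls),
        n_fbls=len(fbls),
    )
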