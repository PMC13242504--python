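"""Canalizing Boolean update rules for signed benchmark networks.

Every non-external node receives a *fully canalizing* update function
consistent with its incoming edge signs: the function is monotonically
increasing in each activator and decreasing in each inhibitor, every
regulator is essential, and the canalizing depth equals the in-degree.

Three rule families are provided:

* **OR-NOT** — the disjunction of signed literals (``x`` for an activator,
  ``NOT x`` for an inhibitor).
* **AND-OR-NOT** — per node either the conjunction or the disjunction of
  signed literals; the per-node choice is a seeded coin unless configured.
* **general canalizing** — a random nested canalizing function over a
  random input order with random layer structure, literal polarities
  forced by the edge signs.

Functions are represented both as a nested canalizing chain
``[(variable, canalizing input a, canalized output b), ...]`` (the first
variable matching its canalizing input decides the output; if none does,
the output is the complement of the last canalized output) and as an
explicit truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Mapping

import numpy as np

from .graphs import DirectedGraph, SignedGraph

__all__ = [
    "BooleanFunction",
    "BooleanNetwork",
    "canalizing_depth",
    "build_or_not",
    "build_and_or_not",
    "build_general_canalizing",
    "assemble_network",
    "interaction_graph",
    "identity_function",
]

Layer = tuple[str, int, int]  # (variable, canalizing input a, canalized output b)


@dataclass(frozen=True)
class BooleanFunction:
    """Boolean function with ordered inputs and explicit truth table.

    ``table[i]`` is the output for the input combination whose bit ``j``
    (least significant first) is the state of ``inputs[j]``.  ``layers``
    optionally records a nested canalizing chain realising the function.
    """

    inputs: tuple[str, ...]
    table: tuple[int, ...]
    layers: tuple[Layer, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.table) != 2 ** len(self.inputs):
            raise ValueError("truth table length must be 2**len(inputs)")
        if any(b not in (0, 1) for b in self.table):
            raise ValueError("truth table entries must be 0/1")
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError("duplicate inputs")

    @property
    def arity(self) -> int:
        return len(self.inputs)

    def __call__(self, state: Mapping[str, int]) -> int:
        idx = 0
        for j, v in enumerate(self.inputs):
            idx |= (state[v] & 1) << j
        return self.table[idx]

    def is_constant(self) -> bool:
        return len(set(self.table)) == 1

    def restrict(self, pos: int, value: int) -> "BooleanFunction":
        """Fix input number ``pos`` to ``value`` and drop it."""
        lo, hi = 1 << pos, 1 << (pos + 1)
        sub = [
            self.table[(i % lo) + (i // lo) * hi + value * lo]
            for i in range(len(self.table) // 2)
        ]
        return BooleanFunction(
            self.inputs[:pos] + self.inputs[pos + 1:], tuple(sub)
        )

    def is_essential(self, pos: int) -> bool:
        return self.restrict(pos, 0).table != self.restrict(pos, 1).table

    def monotone_direction(self, pos: int) -> int | None:
        """+1 if increasing in input ``pos``, -1 if decreasing, 0 if the
        input is not essential, None if non-monotone."""
        t0, t1 = self.restrict(pos, 0).table, self.restrict(pos, 1).table
        if t0 == t1:
            return 0
        up = all(a <= b for a, b in zip(t0, t1))
        down = all(a >= b for a, b in zip(t0, t1))
        if up:
            return +1
        if down:
            return -1
        return None


def identity_function(node: str) -> BooleanFunction:
    """State-copying rule used for external parameters."""
    return BooleanFunction((node,), (0, 1), layers=((node, 1, 1),))


@lru_cache(maxsize=100_000)
def _depth(table: tuple[int, ...], k: int) -> int:
    if k == 0 or len(set(table)) == 1:
        return 0
    best = 0
    f = BooleanFunction(tuple(f"x{i}" for i in range(k)), table)
    for pos in range(k):
        for a in (0, 1):
            fixed = f.restrict(pos, a)
            if fixed.is_constant():
                rest = f.restrict(pos, 1 - a)
                best = max(best, 1 + _depth(rest.table, k - 1))
    return best


def canalizing_depth(f: BooleanFunction) -> int:
    """Largest d such that f admits a nested canalizing chain of length d.

    Computed by recursive truth-table testing over all (variable, input)
    pairs.  Constant functions (and functions with no canalizing variable,
    such as XOR) return 0.  A fully canalizing function has depth equal to
    its number of essential inputs.
    """
    return _depth(f.table, f.arity)


def _table_from_layers(inputs: tuple[str, ...], layers: Iterable[Layer]) -> tuple[int, ...]:
    layers = list(layers)
    pos = {v: j for j, v in enumerate(inputs)}
    out = []
    for idx in range(2 ** len(inputs)):
        val = None
        for v, a, b in layers:
            if (idx >> pos[v]) & 1 == a:
                val = b
                break
        if val is None:
            val = 1 - layers[-1][2]
        out.append(val)
    return tuple(out)


def _layer_params(sign: int, b: int) -> tuple[int, int]:
    """Canalizing input a for a desired canalized output b under a given
    edge sign: monotonicity forces a == b for activators, a == 1 - b for
    inhibitors."""
    a = b if sign == +1 else 1 - b
    return a, b


def _regulators(sg: SignedGraph, node: str) -> tuple[str, ...]:
    order = {v: i for i, v in enumerate(sg.graph.nodes)}
    return tuple(sorted(sg.graph.predecessors(node), key=order.__getitem__))


def _check_node(sg: SignedGraph, node: str) -> tuple[str, ...]:
    regs = _regulators(sg, node)
    if not regs:
        raise ValueError(
            f"node {node!r} has no regulators; external parameters carry no rule"
        )
    for u in regs:
        sg.sign(u, node)  # raises if unsigned
    return regs


def _from_chain(inputs: tuple[str, ...], chain: list[Layer]) -> BooleanFunction:
    return BooleanFunction(inputs, _table_from_layers(inputs, chain), tuple(chain))


def build_or_not(sg: SignedGraph, node: str) -> BooleanFunction:
    """Disjunction of signed literals: OR over activators x, inhibitors NOT x."""
    regs = _check_node(sg, node)
    chain = [(u, _layer_params(sg.sign(u, node), 1)[0], 1) for u in regs]
    return _from_chain(regs, chain)


def build_and_or_not(
    sg: SignedGraph,
    node: str,
    mode: Literal["AND", "OR"] | None = None,
    rng: np.random.Generator | None = None,
) -> BooleanFunction:
    """Conjunction (AND) or disjunction (OR) of signed literals.

    With ``mode=None`` the mode is a Bernoulli(1/2) draw from ``rng``.
    """
    regs = _check_node(sg, node)
    if mode is None:
        if rng is None:
            raise ValueError("either a mode or an rng is required")
        mode = "AND" if rng.integers(2) else "OR"
    b = 0 if mode == "AND" else 1
    chain = [(u, _layer_params(sg.sign(u, node), b)[0], b) for u in regs]
    return _from_chain(regs, chain)


def build_general_canalizing(
    sg: SignedGraph, node: str, rng: np.random.Generator
) -> BooleanFunction:
    """Random nested canalizing function with sign-forced polarities.

    The input order is a random permutation; canalized outputs are grouped
    into layers with geometric(p = 1/2) sizes and alternating output
    values, so the function mixes AND- and OR-like levels.  The result is
    verified fully canalizing and sign-consistent before return.
    """
    regs = _check_node(sg, node)
    order = [regs[i] for i in rng.permutation(len(regs))]
    b = int(rng.integers(2))
    chain: list[Layer] = []
    i = 0
    while i < len(order):
        size = min(1 + int(rng.geometric(0.5) - 1), len(order) - i)
        for v in order[i:i + size]:
            a, _ = _layer_params(sg.sign(v, node), b)
            chain.append((v, a, b))
        i += size
        b = 1 - b
    f = _from_chain(regs, chain)
    _verify_function(f, sg, node)
    return f


def _verify_function(f: BooleanFunction, sg: SignedGraph, node: str) -> None:
    if canalizing_depth(f) != f.arity:
        raise AssertionError(f"function for {node!r} is not fully canalizing")
    for pos, u in enumerate(f.inputs):
        d = f.monotone_direction(pos)
        if d != sg.sign(u, node):
            raise AssertionError(
                f"function for {node!r} violates sign of regulator {u!r}"
            )


@dataclass(frozen=True)
class BooleanNetwork:
    """A signed graph plus canalizing local update functions.

    ``functions`` covers every non-external node; external parameters are
    held constant by the dynamics (identity rule).
    """

    signed: SignedGraph
    functions: dict[str, BooleanFunction]
    external: frozenset[str] = field(default_factory=frozenset)

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.signed.graph.nodes

    @property
    def n(self) -> int:
        return len(self.nodes)

    def function(self, node: str) -> BooleanFunction:
        if node in self.external:
            return identity_function(node)
        return self.functions[node]

    def verify(self) -> None:
        """Assert all structural invariants (inputs match regulators,
        sign consistency, full canalization, externals have no rule)."""
        sg = self.signed
        if not sg.is_total:
            raise AssertionError("signed graph is not totally signed")
        if set(self.external) != set(sg.graph.external_nodes()):
            raise AssertionError("external set must equal the in-degree-0 nodes")
        if set(self.functions) != set(sg.graph.nodes) - set(self.external):
            raise AssertionError("functions must cover exactly the regulated nodes")
        for node, f in self.functions.items():
            if set(f.inputs) != set(sg.graph.predecessors(node)):
                raise AssertionError(f"inputs of {node!r} differ from its regulators")
            _verify_function(f, sg, node)


Family = Literal["OR_NOT", "AND_OR_NOT", "GENERAL"]

FAMILIES: tuple[Family, ...] = ("OR_NOT", "AND_OR_NOT", "GENERAL")


def assemble_network(
    sg: SignedGraph,
    family: Family,
    rng: np.random.Generator | int | None = None,
    modes: Mapping[str, str] | None = None,
) -> BooleanNetwork:
    """Attach a full set of update functions of one family.

    OR_NOT is deterministic; AND_OR_NOT draws per-node modes from ``rng``
    unless ``modes`` overrides them; GENERAL draws random nested
    canalizing functions.  All invariants are verified before return.
    """
    if not sg.is_total:
        raise ValueError("assemble_network requires a totally signed graph")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    external = frozenset(sg.graph.external_nodes())
    functions: dict[str, BooleanFunction] = {}
    for node in sg.graph.nodes:
        if node in external:
            continue
        if family == "OR_NOT":
            functions[node] = build_or_not(sg, node)
        elif family == "AND_OR_NOT":
            mode = modes.get(node) if modes else None
            functions[node] = build_and_or_not(sg, node, mode=mode, rng=rng)
        elif family == "GENERAL":
            if rng is None:
                raise ValueError("GENERAL family requires an rng")
            functions[node] = build_general_canalizing(sg, node, rng)
        else:
            raise ValueError(f"unknown family {family!r}")
    bn = BooleanNetwork(signed=sg, functions=functions, external=external)
    bn.verify()
    return bn


def interaction_graph(bn: BooleanNetwork) -> SignedGraph:
    """Reconstruct the signed graph from the truth tables.

    Every essential input of every update function contributes an edge
    whose sign is the function's monotone direction in that input
    (non-monotone dependence raises: benchmark rules are regulatory).
    External parameters contribute their outgoing edges only.
    """
    nodes = bn.nodes
    g = DirectedGraph(nodes)
    signs: dict[tuple[str, str], int] = {}
    for node, f in bn.functions.items():
        for pos, u in enumerate(f.inputs):
            d = f.monotone_direction(pos)
            if d == 0:
                continue
            if d is None:
                raise ValueError(
                    f"function for {node!r} is non-monotone in {u!r}"
                )
            g.add_edge(u, node)
            signs[(u, node)] = d
    return SignedGraph(g, signs)
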