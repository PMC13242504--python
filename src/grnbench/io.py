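"""Readers and writers for the benchmark file formats.

* **Adjacency CSV** — square matrix with node labels as header row and
  index column; entry (i, j) is nonzero iff there is an edge from row
  node i to column node j (+-1 signed, or 1 unsigned).  ``orientation``
  can be flipped for matrices stored column-as-source; ``load_model``
  auto-detects the orientation by checking the rule file against both.
* **Rule TXT** — the widely used "targets, factors" dialect: one line per
  node, ``target, expression`` with operators ``&``/``AND``, ``|``/``OR``,
  ``!``/``NOT`` and parentheses.  The reader is tolerant about operator
  spelling; the writer is canonical.
* **Config YAML** — all generator/optimizer parameters and kingdom target
  vectors in one structured file.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graphs import DirectedGraph, SignedGraph
from .rules import BooleanFunction, BooleanNetwork
from .signs import OptimizerConfig
from .targets import TargetDistributions
from .topology import GeneratorConfig

__all__ = [
    "write_adjacency",
    "read_adjacency",
    "write_rules",
    "read_rules",
    "load_model",
    "make_fixture",
    "default_config",
    "load_config",
    "dump_config",
]


# ---------------------------------------------------------------------------
# Adjacency matrices
# ---------------------------------------------------------------------------

def write_adjacency(net: DirectedGraph | SignedGraph, path: str | Path) -> None:
    """Write a (signed) graph as an adjacency CSV, rows = source."""
    sg = net if isinstance(net, SignedGraph) else None
    g = sg.graph if sg else net
    m = pd.DataFrame(0, index=list(g.nodes), columns=list(g.nodes), dtype=int)
    for u, v in g.sorted_edges():
        m.loc[u, v] = sg.sign(u, v) if sg else 1
    m.to_csv(path)


def read_adjacency(
    path: str | Path, orientation: str = "row-source"
) -> DirectedGraph | SignedGraph:
    """Read an adjacency CSV; returns a SignedGraph when any entry is -1,
    otherwise a plain DirectedGraph."""
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if list(m.index) != list(m.columns):
        raise ValueError(f"{path}: adjacency matrix must be square with "
                         "matching row/column labels")
    if m.index.duplicated().any():
        raise ValueError(f"{path}: duplicate node labels")
    vals = m.to_numpy()
    bad = ~np.isin(vals, (-1, 0, 1))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: illegal entry {vals[i, j]!r} at row {m.index[i]!r}, "
            f"column {m.columns[j]!r}"
        )
    if orientation == "col-source":
        m = m.T
    elif orientation != "row-source":
        raise ValueError(f"unknown orientation {orientation!r}")
    g = DirectedGraph(list(m.index))
    signs: dict[tuple[str, str], int] = {}
    for u in m.index:
        for v in m.columns:
            s = int(m.loc[u, v])
            if s:
                g.add_edge(u, v)
                signs[(u, v)] = s
    if all(s == 1 for s in signs.values()):
        return g
    return SignedGraph(g, signs)


# ---------------------------------------------------------------------------
# Rule files ("targets, factors" dialect)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|&|\||!|\bAND\b|\bOR\b|\bNOT\b|[A-Za-z_][\w.]*)",
                    re.IGNORECASE)


def _tokenize(expr: str) -> list[str]:
    out, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            if expr[pos:].strip():
                raise ValueError(f"syntax error near {expr[pos:]!r}")
            break
        tok = m.group(1)
        up = tok.upper()
        out.append({"AND": "&", "OR": "|", "NOT": "!"}.get(up, tok))
        pos = m.end()
    return out


class _Parser:
    """expr := term ('|' term)* ; term := factor ('&' factor)* ;
    factor := '!' factor | '(' expr ')' | identifier"""

    def __init__(self, tokens: list[str]):
        self.toks = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of expression")
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens: {self.toks[self.i:]}")
        return node

    def expr(self):
        terms = [self.term()]
        while self.peek() == "|":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def term(self):
        factors = [self.factor()]
        while self.peek() == "&":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def factor(self):
        tok = self.next()
        if tok == "!":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise ValueError("missing closing parenthesis")
            return node
        if tok in ("&", "|", ")"):
            raise ValueError(f"unexpected {tok!r}")
        return ("var", tok)


def _ast_vars(node) -> set[str]:
    kind = node[0]
    if kind == "var":
        return {node[1]}
    if kind == "not":
        return _ast_vars(node[1])
    return set().union(*(_ast_vars(c) for c in node[1]))


def _ast_eval(node, state: dict[str, int]) -> int:
    kind = node[0]
    if kind == "var":
        return state[node[1]]
    if kind == "not":
        return 1 - _ast_eval(node[1], state)
    if kind == "and":
        return int(all(_ast_eval(c, state) for c in node[1]))
    return int(any(_ast_eval(c, state) for c in node[1]))


def _expression(f: BooleanFunction) -> str:
    """Canonical expression from a nested canalizing chain."""
    if f.layers is None:
        raise ValueError("function has no chain representation")
    layers = list(f.layers)

    def lit(v: str, true_when: int) -> str:
        return v if true_when == 1 else f"!{v}"

    def rec(i: int) -> str:
        v, a, b = layers[i]
        if i == len(layers) - 1:
            # terminal: output b iff x_v == a (else the complement)
            return lit(v, a) if b == 1 else lit(v, 1 - a)
        rest = rec(i + 1)
        if len(layers[i + 1:]) > 1:
            rest = f"({rest})"
        if b == 1:  # F = [x_v == a] OR rest
            return f"{lit(v, a)} | {rest}"
        return f"{lit(v, 1 - a)} & {rest}"  # F = [x_v != a] AND rest

    return rec(0)


def write_rules(bn: BooleanNetwork, path: str | Path) -> None:
    """Write one "target, factors" line per node; external parameters get
    the identity rule."""
    lines = ["targets, factors"]
    for node in bn.nodes:
        if node in bn.external:
            lines.append(f"{node}, {node}")
        else:
            lines.append(f"{node}, {_expression(bn.functions[node])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rules(path: str | Path, sg: SignedGraph) -> BooleanNetwork:
    """Parse a rule file and validate it against a signed graph.

    Each parsed function must use exactly the node's regulators as
    essential inputs, respect the edge signs (monotone direction), and be
    fully canalizing; violations raise with the offending node named.
    External parameters may carry an identity line or be omitted.
    """
    from .rules import canalizing_depth

    g = sg.graph
    external = set(g.external_nodes())
    functions: dict[str, BooleanFunction] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.lower().startswith("targets"):
            continue
        if "," not in line:
            raise ValueError(f"{path}:{ln}: expected 'target, expression'")
        target, expr = (part.strip() for part in line.split(",", 1))
        if not g.has_node(target):
            raise ValueError(f"{path}:{ln}: unknown target node {target!r}")
        ast = _Parser(_tokenize(expr)).parse()
        used = _ast_vars(ast)
        unknown = used - set(g.nodes)
        if unknown:
            raise ValueError(f"{path}:{ln}: unknown variable(s) {sorted(unknown)}")
        if target in external:
            if used != {target}:
                raise ValueError(
                    f"{path}:{ln}: external parameter {target!r} must keep "
                    "the identity rule"
                )
            continue
        order = {v: i for i, v in enumerate(g.nodes)}
        inputs = tuple(sorted(g.predecessors(target), key=order.__getitem__))
        if used != set(inputs):
            raise ValueError(
                f"{path}:{ln}: rule variables {sorted(used)} differ from "
                f"regulators {sorted(inputs)} of {target!r}"
            )
        table = []
        for idx in range(2 ** len(inputs)):
            state = {v: (idx >> j) & 1 for j, v in enumerate(inputs)}
            table.append(_ast_eval(ast, state))
        f = BooleanFunction(inputs, tuple(table))
        for pos, u in enumerate(inputs):
            d = f.monotone_direction(pos)
            if d == 0:
                raise ValueError(
                    f"{path}:{ln}: regulator {u!r} of {target!r} is not essential"
                )
            if d != sg.sign(u, target):
                raise ValueError(
                    f"{path}:{ln}: rule for {target!r} contradicts the sign "
                    f"of edge ({u!r} -> {target!r})"
                )
        if canalizing_depth(f) != len(inputs):
            raise ValueError(
                f"{path}:{ln}: rule for {target!r} is not fully canalizing"
            )
        functions[target] = f
    missing = set(g.nodes) - external - set(functions)
    if missing:
        raise ValueError(f"{path}: missing rules for {sorted(missing)}")
    return BooleanNetwork(signed=sg, functions=functions,
                          external=frozenset(external))


def find_adjacency(directory: str | Path) -> Path:
    """First CSV in a directory that parses as an adjacency matrix
    (directories may also hold report CSVs)."""
    directory = Path(directory)
    errors = []
    for candidate in sorted(directory.glob("*.csv")):
        try:
            read_adjacency(candidate)
            return candidate
        except ValueError as exc:
            errors.append(str(exc))
    raise FileNotFoundError(
        f"no adjacency CSV in {directory}" + ("; " + "; ".join(errors) if errors else "")
    )


def load_model(directory: str | Path, rules_name: str | None = None):
    """Load a model directory (adjacency CSV + optional rule TXT).

    When a rule file is present, the adjacency orientation is
    auto-detected by validating the rules against both conventions.
    """
    directory = Path(directory)
    adj = find_adjacency(directory)
    rule_paths = (
        [directory / rules_name] if rules_name else sorted(directory.glob("*.txt"))
    )
    net = read_adjacency(adj)
    if not rule_paths or not isinstance(net, SignedGraph):
        return net, None
    try:
        return net, read_rules(rule_paths[0], net)
    except ValueError:
        flipped = read_adjacency(adj, orientation="col-source")
        return flipped, read_rules(rule_paths[0], flipped)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0, **params):
    """Small deterministic instances with known ground truth.

    ``toy_ffl`` — 3 nodes, one FFL; ``toy_cycle`` — a single directed
    cycle of ``length`` nodes; ``random_small`` — reproducible random
    digraph with ``n`` nodes and edge probability ``p``.
    """
    if kind == "toy_ffl":
        return DirectedGraph("abc", [("a", "b"), ("b", "c"), ("a", "c")])
    if kind == "toy_cycle":
        length = int(params.get("length", 4))
        labels = [f"c{i}" for i in range(length)]
        edges = [(labels[i], labels[(i + 1) % length]) for i in range(length)]
        return DirectedGraph(labels, edges)
    if kind == "random_small":
        n = int(params.get("n", 8))
        p = float(params.get("p", 0.25))
        rng = np.random.default_rng(seed)
        labels = [f"n{i}" for i in range(n)]
        edges = [
            (labels[i], labels[j])
            for i in range(n)
            for j in range(n)
            if rng.random() < p
        ]
        return DirectedGraph(labels, edges)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

CONFIG_VERSION = 1


def default_config() -> dict:
    t = TargetDistributions()
    o = OptimizerConfig()
    gcfg = GeneratorConfig()
    return {
        "version": CONFIG_VERSION,
        "generator": {
            "n": gcfg.n,
            "max_iterations": gcfg.max_iterations,
            "n_restarts": gcfg.n_restarts,
            "rng_seed": gcfg.rng_seed,
            "stage_weights": list(gcfg.stage_weights),
            "tolerance": gcfg.tolerance,
            "edge_band": gcfg.edge_band,
        },
        "optimizer": {
            "n_candidates": o.n_candidates,
            "n_iterations": o.n_iterations,
            "weights": list(o.weights),
            "M_L_grid": [list(ml) for ml in o.M_L_grid],
            "pool_size": o.pool_size,
            "max_open": o.max_open,
            "rng_seed": o.rng_seed,
        },
        "targets": {
            "gamma": t.gamma,
            "k_out_min": t.k_out_min,
            "poisson_rate": t.poisson_rate,
            "mean_connectivity": t.mean_connectivity,
            "n_external": t.n_external,
            "ffl_cluster_freq": list(t.ffl_cluster_freq),
            "ffl_type_freq": {k: list(v) for k, v in t.ffl_type_freq.items()},
            "fbl_positive_frac": {k: list(v) for k, v in t.fbl_positive_frac.items()},
            "pos_input_frac": {
                k: {int(d): f for d, f in v.items()}
                for k, v in t.pos_input_frac.items()
            },
        },
    }


def _build_configs(cfg: dict) -> tuple[GeneratorConfig, OptimizerConfig, TargetDistributions]:
    tc = cfg.get("targets", {})
    targets = TargetDistributions(
        gamma=tc.get("gamma", 2.0),
        k_out_min=tc.get("k_out_min", 1),
        poisson_rate=tc.get("poisson_rate", 2.5),
        mean_connectivity=tc.get("mean_connectivity", 2.5),
        n_external=tc.get("n_external", 1),
        ffl_cluster_freq=tuple(
            tc.get("ffl_cluster_freq", TargetDistributions().ffl_cluster_freq)
        ),
        ffl_type_freq={
            k: tuple(v)
            for k, v in tc.get(
                "ffl_type_freq", TargetDistributions().ffl_type_freq
            ).items()
        },
        fbl_positive_frac={
            k: tuple(v)
            for k, v in tc.get(
                "fbl_positive_frac", TargetDistributions().fbl_positive_frac
            ).items()
        },
        pos_input_frac={
            k: {int(d): float(f) for d, f in v.items()}
            for k, v in tc.get(
                "pos_input_frac", TargetDistributions().pos_input_frac
            ).items()
        },
    )
    gc = cfg.get("generator", {})
    gen = GeneratorConfig(
        n=gc.get("n", 20),
        targets=targets,
        max_iterations=gc.get("max_iterations", 4000),
        n_restarts=gc.get("n_restarts", 2),
        rng_seed=gc.get("rng_seed", 0),
        stage_weights=tuple(gc.get("stage_weights", (0.2,) * 5)),
        tolerance=gc.get("tolerance", 0.02),
        edge_band=gc.get("edge_band", 0.10),
    )
    oc = cfg.get("optimizer", {})
    opt = OptimizerConfig(
        n_candidates=oc.get("n_candidates", 25),
        n_iterations=oc.get("n_iterations", 1000),
        weights=tuple(oc.get("weights", (1 / 3, 1 / 3, 1 / 3))),
        M_L_grid=tuple(tuple(ml) for ml in oc.get("M_L_grid",
                       ((4, 2), (6, 3), (8, 4), (10, 5)))),
        pool_size=oc.get("pool_size", 5000),
        max_open=oc.get("max_open", 20),
        rng_seed=oc.get("rng_seed", 0),
    )
    return gen, opt, targets


def load_config(path: str | Path | None):
    """Load (GeneratorConfig, OptimizerConfig, TargetDistributions) from a
    YAML file; None loads the shipped defaults."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if isinstance(values, dict) and section in cfg:
                cfg[section].update(values)
            else:
                cfg[section] = values
    return _build_configs(cfg)


def dump_config(path: str | Path | None = None) -> str:
    text = yaml.safe_dump(default_config(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
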