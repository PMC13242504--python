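"""Kingdom-specific sign assignment by weighted-error search.

Signs (+1 activating, -1 inhibiting) are fitted to the underlying topology
in two stages.  First, random sign assignments restricted to the edges
that participate in feed-forward loops are scored against the kingdom's
target distribution of the 8 signed FFL types, and the best
``n_candidates`` partial signings are kept as seeds.  Second, each seed is
completed: the free (non-FFL) edges are signed at random until ``M``
remain open, ``L`` FFL edges are reopened (drawn by inverse
FFL-membership frequency, so rarely used edges are more likely), and all
``2**(M+L)`` assignments of the open edges are evaluated exhaustively.
The objective is the weighted error over three sign-motif statistics —
FFL-type distribution, fraction of positive feedback loops by length, and
fraction of activating inputs by in-degree — with default weights 1/3
each.  The routine repeats for ``n_iterations`` per (M, L) pair, and the
best network across all seeds is returned.

All randomness is seeded; ties are broken toward the lexicographically
smallest sign vector (+ before -), so results are reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graphs import DirectedGraph, SignedGraph
from .motifs import FFL_TYPE_BY_SIGNS, enumerate_fbls, enumerate_ffls
from .targets import MAX_FBL_LEN, N_FFL_TYPES, TargetDistributions

__all__ = [
    "OptimizerConfig",
    "SignFitError",
    "SeedCandidate",
    "CompletionResult",
    "KingdomResult",
    "ffl_edge_importance",
    "seed_ffl_candidates",
    "sign_fit_error",
    "complete_signs",
    "optimize_kingdom",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class OptimizerConfig:
    n_candidates: int = 25
    n_iterations: int = 1000
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    M_L_grid: tuple[tuple[int, int], ...] = ((4, 2), (6, 3), (8, 4), (10, 5))
    pool_size: int = 5000
    max_open: int = 20  # cap on M + L, guards 2**(M+L) exhaustion
    max_fbl_len: int = MAX_FBL_LEN
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 1 or self.n_iterations < 1 or self.pool_size < 1:
            raise ValueError("counts must be positive")
        w = self.weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be 3 nonnegative values summing to 1")
        for m, l in self.M_L_grid:
            if m < 0 or l < 0 or m + l > self.max_open:
                raise ValueError(f"(M, L) = ({m}, {l}) violates the M+L cap")


@dataclass(frozen=True)
class SignFitError:
    ffl_err: float
    fbl_err: float
    indeg_err: float
    total: float


@dataclass(frozen=True)
class SeedCandidate:
    signed: SignedGraph  # partial: FFL edges only
    score: float  # distance of realised FFL-type distribution to target


@dataclass(frozen=True)
class CompletionResult:
    signed: SignedGraph
    error: SignFitError
    n_evaluations: int
    evaluations_per_pass: tuple[int, ...]


@dataclass(frozen=True)
class KingdomResult:
    kingdom: str
    signed: SignedGraph
    error: SignFitError
    per_seed_errors: tuple[float, ...]
    n_evaluations: int


# ---------------------------------------------------------------------------
# Precomputed evaluation machinery
# ---------------------------------------------------------------------------

def _type_code_table() -> np.ndarray:
    """code (bit 0 = uv, 1 = vw, 2 = uw; bit set means minus) -> type index 0-7."""
    out = np.zeros(8, dtype=np.int64)
    for code in range(8):
        triple = tuple(-1 if (code >> b) & 1 else +1 for b in range(3))
        out[code] = FFL_TYPE_BY_SIGNS[triple].type_id - 1
    return out


_TYPE_OF_CODE = _type_code_table()


class _SignProblem:
    """Edge-indexed view of one sign-fitting instance.

    Evaluates sign vectors (np arrays of +-1 aligned with the graph's
    sorted edge list) against the kingdom's three target distributions,
    scalar or batched.
    """

    def __init__(
        self,
        g: DirectedGraph,
        targets: TargetDistributions,
        kingdom: str,
        weights: tuple[float, float, float],
        max_fbl_len: int = MAX_FBL_LEN,
    ):
        self.graph = g
        self.kingdom = kingdom
        self.weights = weights
        self.edges: list[Edge] = g.sorted_edges()
        self.edge_index = {e: i for i, e in enumerate(self.edges)}

        ffls = enumerate_ffls(g)
        self.ffl_triples = np.array(
            [
                [
                    self.edge_index[(f.u, f.v)],
                    self.edge_index[(f.v, f.w)],
                    self.edge_index[(f.u, f.w)],
                ]
                for f in ffls
            ],
            dtype=np.int64,
        ).reshape(-1, 3)
        self.ffl_edges: list[Edge] = sorted(
            {e for f in ffls for e in f.edge_set}, key=self.edge_index.__getitem__
        )
        self.free_edges: list[Edge] = [
            e for e in self.edges if e not in set(self.ffl_edges)
        ]
        self.type_target = np.asarray(targets.ffl_type_freq[kingdom], dtype=float)

        fbls = enumerate_fbls(g, max_fbl_len)
        self.fbl_groups = {
            m: [
                np.array([self.edge_index[e] for e in f.edges()], dtype=np.int64)
                for f in fbls
                if f.length == m
            ]
            for m in range(1, max_fbl_len + 1)
        }
        self.fbl_target = {
            m: targets.fbl_positive_frac[kingdom][m - 1]
            for m in range(1, max_fbl_len + 1)
        }

        self.indeg_groups: dict[int, np.ndarray] = {}
        self.indeg_target: dict[int, float] = {}
        by_k: dict[int, list[int]] = {}
        for v in g.nodes:
            k = g.in_degree(v)
            if k == 0:
                continue
            by_k.setdefault(k, []).extend(
                self.edge_index[(u, v)] for u in g.predecessors(v)
            )
        for k, idxs in by_k.items():
            self.indeg_groups[k] = np.array(sorted(idxs), dtype=np.int64)
            self.indeg_target[k] = targets.pos_input_target(kingdom, k)

    # -- batched error over P sign vectors (P, n_edges) -----------------
    def ffl_errors(self, signs: np.ndarray) -> np.ndarray:
        p = signs.shape[0]
        if len(self.ffl_triples) == 0:
            return np.zeros(p)
        tri = signs[:, self.ffl_triples]  # (P, F, 3)
        neg = (tri < 0).astype(np.int64)
        codes = neg[:, :, 0] | (neg[:, :, 1] << 1) | (neg[:, :, 2] << 2)
        types = _TYPE_OF_CODE[codes]  # (P, F)
        counts = np.zeros((p, N_FFL_TYPES), dtype=np.int64)
        np.add.at(counts, (np.arange(p)[:, None], types), 1)
        freq = counts / counts.sum(axis=1, keepdims=True)
        return 0.5 * np.abs(freq - self.type_target[None, :]).sum(axis=1)

    def fbl_errors(self, signs: np.ndarray) -> np.ndarray:
        p = signs.shape[0]
        errs = np.zeros(p)
        occupied = 0
        for m, cycles in self.fbl_groups.items():
            if not cycles:
                continue
            occupied += 1
            pos = np.zeros(p)
            for cyc in cycles:
                pos += (signs[:, cyc].prod(axis=1) > 0)
            errs += np.abs(pos / len(cycles) - self.fbl_target[m])
        return errs / occupied if occupied else errs

    def indeg_errors(self, signs: np.ndarray) -> np.ndarray:
        p = signs.shape[0]
        errs = np.zeros(p)
        if not self.indeg_groups:
            return errs
        for k, idxs in self.indeg_groups.items():
            frac = (signs[:, idxs] > 0).mean(axis=1)
            errs += np.abs(frac - self.indeg_target[k])
        return errs / len(self.indeg_groups)

    def totals(self, signs: np.ndarray) -> np.ndarray:
        w = self.weights
        return (
            w[0] * self.ffl_errors(signs)
            + w[1] * self.fbl_errors(signs)
            + w[2] * self.indeg_errors(signs)
        )

    def error(self, signs: np.ndarray) -> SignFitError:
        s = signs[None, :]
        f, b, i = (
            float(self.ffl_errors(s)[0]),
            float(self.fbl_errors(s)[0]),
            float(self.indeg_errors(s)[0]),
        )
        w = self.weights
        return SignFitError(f, b, i, w[0] * f + w[1] * b + w[2] * i)

    def to_signed(self, signs: np.ndarray) -> SignedGraph:
        return SignedGraph(
            self.graph, {e: int(s) for e, s in zip(self.edges, signs)}
        )

    def vector(self, sg: SignedGraph, fill: int = 0) -> np.ndarray:
        v = np.full(len(self.edges), fill, dtype=np.int8)
        for e, s in sg.signs.items():
            v[self.edge_index[e]] = s
        return v


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def ffl_edge_importance(g: DirectedGraph) -> dict[Edge, float]:
    """Selection weight per FFL edge, proportional to the inverse of the
    number of FFLs the edge participates in; weights sum to 1.  Edges
    outside any FFL are absent."""
    counts: dict[Edge, int] = {}
    for f in enumerate_ffls(g):
        for e in f.edge_set:
            counts[e] = counts.get(e, 0) + 1
    if not counts:
        return {}
    raw = {e: 1.0 / c for e, c in counts.items()}
    z = sum(raw.values())
    return {e: w / z for e, w in raw.items()}


def _lex_key(signs: np.ndarray) -> tuple[int, ...]:
    return tuple(0 if s > 0 else 1 for s in signs)


def seed_ffl_candidates(
    g: DirectedGraph,
    targets: TargetDistributions,
    cfg: OptimizerConfig,
    kingdom: str,
    rng: np.random.Generator | None = None,
) -> list[SeedCandidate]:
    """Best partially signed candidates over the FFL edges.

    Draws ``pool_size`` random sign assignments restricted to the FFL
    edges, scores each by the distance between the realised and target
    FFL-type distributions, and returns the ``n_candidates`` best distinct
    assignments (score ties broken lexicographically, + before -).  If the
    graph has no FFLs, a single empty partial signing is returned.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    prob = _SignProblem(g, targets, kingdom, cfg.weights, cfg.max_fbl_len)
    if len(prob.ffl_triples) == 0:
        import warnings

        warnings.warn("graph has no FFLs; returning one empty partial signing",
                      stacklevel=2)
        return [SeedCandidate(SignedGraph(g, {}), 0.0)]
    ffl_idx = np.array([prob.edge_index[e] for e in prob.ffl_edges])
    n_open = len(ffl_idx)
    if n_open <= cfg.max_open and 2 ** n_open <= cfg.pool_size:
        draws = np.array(list(itertools.product((1, -1), repeat=n_open)), dtype=np.int8)
    else:
        draws = rng.choice(np.array([1, -1], dtype=np.int8),
                           size=(cfg.pool_size, n_open))
        draws = np.unique(draws, axis=0)
    full = np.ones((draws.shape[0], len(prob.edges)), dtype=np.int8)
    full[:, ffl_idx] = draws
    scores = prob.ffl_errors(full)
    order = sorted(range(len(draws)),
                   key=lambda i: (scores[i], _lex_key(draws[i])))
    out = []
    for i in order[: cfg.n_candidates]:
        signs = {prob.ffl_edges[j]: int(draws[i, j]) for j in range(n_open)}
        out.append(SeedCandidate(SignedGraph(g, signs), float(scores[i])))
    return out


def sign_fit_error(
    sg: SignedGraph,
    targets: TargetDistributions,
    kingdom: str,
    cfg: OptimizerConfig | None = None,
) -> SignFitError:
    """Weighted three-distribution error of a totally signed graph.

    The FFL component is the distance between realised and target type
    distributions; the FBL and in-degree components average absolute
    fraction errors over occupied bins only.
    """
    if not sg.is_total:
        raise ValueError("sign_fit_error requires a totally signed graph")
    if cfg is None:
        cfg = OptimizerConfig()
    prob = _SignProblem(sg.graph, targets, kingdom, cfg.weights, cfg.max_fbl_len)
    return prob.error(prob.vector(sg))


def complete_signs(
    partial: SignedGraph,
    targets: TargetDistributions,
    cfg: OptimizerConfig,
    kingdom: str,
    rng: np.random.Generator | None = None,
) -> CompletionResult:
    """Complete a partial (FFL-edge) signing to the best total signing.

    Per iteration and per (M, L) of the grid: free edges are signed at
    random until ``min(M, #free)`` remain open (M is clamped with a
    warning when it exceeds the free-edge count), ``L`` FFL edges are
    reopened by importance-weighted draw without replacement, and all
    ``2**(M+L)`` assignments of the open edges are evaluated.  The best
    total error wins; exact ties go to the lexicographically smallest
    sign vector.  Evaluation counts per exhaustive pass are recorded.
    """
    import warnings

    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    g = partial.graph
    prob = _SignProblem(g, targets, kingdom, cfg.weights, cfg.max_fbl_len)
    base = prob.vector(partial)

    free_idx = np.array(
        [prob.edge_index[e] for e in prob.free_edges], dtype=np.int64
    )
    ffl_idx = np.array(
        [prob.edge_index[e] for e in prob.ffl_edges], dtype=np.int64
    )
    importance = ffl_edge_importance(g)
    imp_p = (
        np.array([importance[e] for e in prob.ffl_edges])
        if len(ffl_idx)
        else np.array([])
    )

    best_signs: np.ndarray | None = None
    best_total = np.inf
    best_key: tuple[int, ...] | None = None
    passes: list[int] = []

    for M, L in cfg.M_L_grid:
        m_eff = min(M, len(free_idx))
        if m_eff < M:
            warnings.warn(
                f"M = {M} exceeds the {len(free_idx)} free edges; clamped",
                stacklevel=2,
            )
        l_eff = min(L, len(ffl_idx))
        if m_eff + l_eff > cfg.max_open:
            raise ValueError(f"M + L = {m_eff + l_eff} exceeds cap {cfg.max_open}")
        for _ in range(cfg.n_iterations):
            signs = base.copy()
            if len(free_idx):
                signs[free_idx] = rng.choice(
                    np.array([1, -1], dtype=np.int8), size=len(free_idx)
                )
            open_free = (
                rng.choice(free_idx, size=m_eff, replace=False)
                if m_eff
                else np.array([], dtype=np.int64)
            )
            open_ffl = (
                rng.choice(ffl_idx, size=l_eff, replace=False, p=imp_p)
                if l_eff
                else np.array([], dtype=np.int64)
            )
            open_idx = np.sort(np.concatenate([open_free, open_ffl]))
            k = len(open_idx)
            combos = np.array(
                list(itertools.product((1, -1), repeat=k)), dtype=np.int8
            ).reshape(-1, max(k, 0))
            batch = np.repeat(signs[None, :], len(combos), axis=0)
            if k:
                batch[:, open_idx] = combos
            totals = prob.totals(batch)
            passes.append(len(combos))
            i = int(np.argmin(totals))  # first minimum = lex-smallest combo
            if totals[i] < best_total - 1e-15:
                best_total = float(totals[i])
                best_signs = batch[i].copy()
                best_key = _lex_key(best_signs)
            elif (
                best_signs is not None
                and abs(totals[i] - best_total) <= 1e-15
                and _lex_key(batch[i]) < best_key
            ):
                best_signs = batch[i].copy()
                best_key = _lex_key(best_signs)

    assert best_signs is not None
    return CompletionResult(
        signed=prob.to_signed(best_signs),
        error=prob.error(best_signs),
        n_evaluations=int(sum(passes)),
        evaluations_per_pass=tuple(passes),
    )


def optimize_kingdom(
    g: DirectedGraph,
    kingdom: str,
    targets: TargetDistributions,
    cfg: OptimizerConfig,
) -> KingdomResult:
    """Full two-stage sign assignment for one kingdom.

    Seeds ``n_candidates`` partial FFL signings, completes each, and
    returns the overall best-fitting totally signed network.  Each seed's
    completion uses an independent child stream of the configured seed, so
    results are deterministic and order-independent across kingdoms.
    """
    root = np.random.SeedSequence(
        [cfg.rng_seed, sum(kingdom.encode())]
    )
    seed_rng, *children = [
        np.random.default_rng(s) for s in root.spawn(cfg.n_candidates + 1)
    ]
    seeds = seed_ffl_candidates(g, targets, cfg, kingdom, rng=seed_rng)
    best: CompletionResult | None = None
    per_seed = []
    n_eval = 0
    for cand, child in zip(seeds, children):
        res = complete_signs(cand.signed, targets, cfg, kingdom, rng=child)
        per_seed.append(res.error.total)
        n_eval += res.n_evaluations
        if best is None or res.error.total < best.error.total:
            best = res
    assert best is not None
    return KingdomResult(
        kingdom=kingdom,
        signed=best.signed,
        error=best.error,
        per_seed_errors=tuple(per_seed),
        n_evaluations=n_eval,
    )
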