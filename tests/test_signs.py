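import itertools

import numpy as np
import pytest

from grnbench import (
    DirectedGraph,
    OptimizerConfig,
    SignedGraph,
    complete_signs,
    distribution_distance,
    enumerate_ffls,
    ffl_edge_importance,
    optimize_kingdom,
    seed_ffl_candidates,
    sign_fit_error,
)
from grnbench.motifs import (
    ffl_type_counts,
    positive_fbl_fraction,
    positive_input_fraction,
)


@pytest.fixture(scope="module")
def toy_graph():
    """One FFL (a, b, c) plus a free 2-cycle and a free chain edge."""
    return DirectedGraph(
        "abcde",
        [("a", "b"), ("b", "c"), ("a", "c"),  # FFL edges
         ("c", "d"), ("d", "c"),              # free 2-cycle
         ("d", "e")],                          # free edge
    )


def naive_fit_error(sg, targets, kingdom, weights=(1 / 3, 1 / 3, 1 / 3)):
    """Independent recomputation from the census primitives."""
    ffls = enumerate_ffls(sg.graph)
    if ffls:
        counts = ffl_type_counts(sg, ffls)
        ffl_err = distribution_distance(
            [counts[i] for i in range(1, 9)], targets.ffl_type_freq[kingdom]
        )
    else:
        ffl_err = 0.0
    fracs = positive_fbl_fraction(sg)
    occupied = [
        (m, f) for m, f in fracs.items() if f is not None
    ]
    fbl_err = (
        sum(abs(f - targets.fbl_positive_frac[kingdom][m - 1]) for m, f in occupied)
        / len(occupied)
        if occupied
        else 0.0
    )
    by_k = positive_input_fraction(sg)
    indeg_err = (
        sum(abs(f - targets.pos_input_target(kingdom, k)) for k, f in by_k.items())
        / len(by_k)
        if by_k
        else 0.0
    )
    return (
        weights[0] * ffl_err + weights[1] * fbl_err + weights[2] * indeg_err,
        ffl_err, fbl_err, indeg_err,
    )


class TestFFLEdgeImportance:
    def test_inverse_frequency_weighting(self):
        # edge (a, b) in one FFL; (a, c) and (c, d)... construct explicitly:
        g = DirectedGraph(
            "abcd",
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("a", "d")],
        )
        # FFLs: (a,b,c) and (a,c,d); edge (a,c) belongs to both
        w = ffl_edge_importance(g)
        assert w[("a", "b")] == pytest.approx(2 * w[("a", "c")])
        assert sum(w.values()) == pytest.approx(1.0)

    def test_non_ffl_edges_absent(self, toy_graph):
        w = ffl_edge_importance(toy_graph)
        assert set(w) == {("a", "b"), ("b", "c"), ("a", "c")}

    def test_no_ffls_empty(self):
        assert ffl_edge_importance(DirectedGraph("ab", [("a", "b")])) == {}


class TestSeedCandidates:
    def test_concentrated_target_selects_all_positive(self, toy_graph, targets):
        t = targets
        import dataclasses

        t2 = dataclasses.replace(
            t, ffl_type_freq={"animal": (1.0,) + (0.0,) * 7}
        )
        cfg = OptimizerConfig(n_candidates=3, pool_size=100, rng_seed=0)
        cands = seed_ffl_candidates(toy_graph, t2, cfg, "animal")
        best = cands[0]
        assert all(s == +1 for s in best.signed.signs.values())
        assert best.score == 0.0

    def test_count_and_ordering(self, toy_graph, targets):
        cfg = OptimizerConfig(n_candidates=8, pool_size=64, rng_seed=0)
        cands = seed_ffl_candidates(toy_graph, targets, cfg, "plant")
        assert len(cands) == 8
        scores = [c.score for c in cands]
        assert scores == sorted(scores)
        for c in cands:
            # partial: exactly the FFL edges are signed
            assert set(c.signed.signs) == {("a", "b"), ("b", "c"), ("a", "c")}

    def test_no_ffls_returns_empty_partial(self, targets):
        g = DirectedGraph("ab", [("a", "b")])
        cfg = OptimizerConfig(rng_seed=0)
        with pytest.warns(UserWarning, match="no FFLs"):
            (cand,) = seed_ffl_candidates(g, targets, cfg, "animal")
        assert cand.signed.signs == {}


class TestSignFitError:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_recomputation(self, toy_graph, targets, seed):
        rng = np.random.default_rng(seed)
        signs = {
            e: int(rng.choice([1, -1])) for e in toy_graph.sorted_edges()
        }
        sg = SignedGraph(toy_graph, signs)
        err = sign_fit_error(sg, targets, "fungi")
        total, f, b, i = naive_fit_error(sg, targets, "fungi")
        assert err.ffl_err == pytest.approx(f)
        assert err.fbl_err == pytest.approx(b)
        assert err.indeg_err == pytest.approx(i)
        assert err.total == pytest.approx(total)

    def test_weights_isolate_components(self, toy_graph, targets):
        sg = SignedGraph(toy_graph, {e: 1 for e in toy_graph.edges})
        cfg = OptimizerConfig(weights=(1.0, 0.0, 0.0))
        err = sign_fit_error(sg, targets, "animal", cfg)
        assert err.total == pytest.approx(err.ffl_err)

    def test_flipping_one_sign_recomputes(self, toy_graph, targets):
        signs = {e: 1 for e in toy_graph.edges}
        e0 = ("a", "c")
        sg = SignedGraph(toy_graph, signs)
        flipped = sg.with_signs({e0: -1})
        err0 = sign_fit_error(sg, targets, "animal")
        err1 = sign_fit_error(flipped, targets, "animal")
        assert err1.total == pytest.approx(
            naive_fit_error(flipped, targets, "animal")[0]
        )
        assert err0.total != err1.total

    def test_partial_signing_rejected(self, toy_graph, targets):
        sg = SignedGraph(toy_graph, {("a", "b"): 1})
        with pytest.raises(ValueError, match="totally signed"):
            sign_fit_error(sg, targets, "animal")


class TestCompleteSigns:
    def test_evaluation_counts_are_powers_of_two(self, toy_graph, targets):
        cfg = OptimizerConfig(
            n_candidates=1, n_iterations=3, M_L_grid=((1, 1),), rng_seed=0
        )
        seed = seed_ffl_candidates(toy_graph, targets, cfg, "animal")[0]
        res = complete_signs(seed.signed, targets, cfg, "animal")
        assert res.evaluations_per_pass == (4, 4, 4)  # 2**(M+L) each
        assert res.n_evaluations == 12

    def test_total_signing_returned(self, toy_graph, targets):
        cfg = OptimizerConfig(
            n_candidates=1, n_iterations=2, M_L_grid=((2, 1),), rng_seed=3
        )
        seed = seed_ffl_candidates(toy_graph, targets, cfg, "plant")[0]
        res = complete_signs(seed.signed, targets, cfg, "plant")
        assert res.signed.is_total

    def test_matches_global_brute_force_when_all_edges_open(
        self, toy_graph, targets
    ):
        """With M covering all free edges and L all FFL edges, one
        exhaustive pass must find the global optimum over 2^|E|."""
        n_free, n_ffl = 3, 3
        cfg = OptimizerConfig(
            n_candidates=1, n_iterations=1, M_L_grid=((n_free, n_ffl),),
            rng_seed=0,
        )
        seed = seed_ffl_candidates(toy_graph, targets, cfg, "bacteria")[0]
        res = complete_signs(seed.signed, targets, cfg, "bacteria")
        assert res.n_evaluations == 2 ** 6

        edges = toy_graph.sorted_edges()
        best = min(
            (
                sign_fit_error(
                    SignedGraph(toy_graph, dict(zip(edges, combo))),
                    targets, "bacteria", cfg,
                ).total
            )
            for combo in itertools.product((1, -1), repeat=len(edges))
        )
        assert res.error.total == pytest.approx(best)

    def test_m_clamped_with_warning(self, toy_graph, targets):
        cfg = OptimizerConfig(
            n_candidates=1, n_iterations=1, M_L_grid=((10, 0),), rng_seed=0
        )
        seed = seed_ffl_candidates(toy_graph, targets, cfg, "animal")[0]
        with pytest.warns(UserWarning, match="clamped"):
            res = complete_signs(seed.signed, targets, cfg, "animal")
        assert res.evaluations_per_pass == (2 ** 3,)  # only 3 free edges


class TestOptimizeKingdom:
    def test_best_across_seeds_is_minimum(self, toy_graph, targets):
        cfg = OptimizerConfig(
            n_candidates=4, n_iterations=3, M_L_grid=((2, 1),),
            pool_size=64, rng_seed=9,
        )
        res = optimize_kingdom(toy_graph, "animal", targets, cfg)
        assert res.error.total <= min(res.per_seed_errors) + 1e-12
        assert len(res.per_seed_errors) == 4

    def test_determinism_under_seed(self, toy_graph, targets):
        cfg = OptimizerConfig(
            n_candidates=2, n_iterations=2, M_L_grid=((2, 1),),
            pool_size=32, rng_seed=5,
        )
        a = optimize_kingdom(toy_graph, "fungi", targets, cfg)
        b = optimize_kingdom(toy_graph, "fungi", targets, cfg)
        assert a.signed.signs == b.signed.signs
        assert a.error == b.error

    def test_kingdoms_share_unsigned_topology(
        self, underlying, targets, tiny_opt_cfg
    ):
        results = {
            k: optimize_kingdom(underlying, k, targets, tiny_opt_cfg)
            for k in ("animal", "bacteria")
        }
        for res in results.values():
            assert res.signed.graph == underlying
            assert res.signed.is_total

    def test_run_order_independence(self, toy_graph, targets):
        """Optimizing kingdom B after A equals optimizing B alone."""
        cfg = OptimizerConfig(
            n_candidates=2, n_iterations=2, M_L_grid=((2, 1),),
            pool_size=32, rng_seed=5,
        )
        optimize_kingdom(toy_graph, "animal", targets, cfg)
        after = optimize_kingdom(toy_graph, "plant", targets, cfg)
        alone = optimize_kingdom(toy_graph, "plant", targets, cfg)
        assert after.signed.signs == alone.signed.signs


class TestOptimizerConfigDefaults:
    def test_paper_defaults(self):
        cfg = OptimizerConfig()
        assert cfg.n_candidates == 25
        assert cfg.n_iterations == 1000
        assert cfg.weights == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            OptimizerConfig(M_L_grid=((15, 10),))
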