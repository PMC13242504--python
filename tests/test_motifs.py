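import itertools

import pytest

from grnbench import (
    DirectedGraph,
    SignedGraph,
    census_report,
    classify_ffl,
    enumerate_clusters,
    enumerate_fbls,
    enumerate_ffls,
    fbl_sign,
    path_sign,
)
from grnbench.motifs import FFL
from grnbench.io import make_fixture

from conftest import random_signed


def brute_force_ffls(g: DirectedGraph):
    """O(n^3) oracle over all ordered node triples."""
    return sorted(
        FFL(u, v, w)
        for u, v, w in itertools.permutations(g.nodes, 3)
        if g.has_edge(u, v) and g.has_edge(v, w) and g.has_edge(u, w)
    )


class TestEnumerateFFLs:
    def test_toy_ffl(self, toy_ffl):
        assert enumerate_ffls(toy_ffl) == [FFL("a", "b", "c")]

    def test_three_cycle_has_none(self):
        assert enumerate_ffls(make_fixture("toy_cycle", length=3)) == []

    def test_self_loops_never_participate(self):
        g = DirectedGraph("abc", [("a", "a"), ("a", "b"), ("b", "c"), ("a", "c")])
        assert enumerate_ffls(g) == [FFL("a", "b", "c")]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_cubic_oracle(self, seed):
        g = make_fixture("random_small", seed=seed, n=7, p=0.35)
        assert enumerate_ffls(g) == brute_force_ffls(g)

    @pytest.mark.parametrize("seed", range(4))
    def test_count_invariant_under_relabeling(self, seed):
        g = make_fixture("random_small", seed=seed, n=7, p=0.35)
        relabel = {v: f"z{i}" for i, v in enumerate(reversed(g.nodes))}
        h = DirectedGraph(
            sorted(relabel.values()),
            [(relabel[u], relabel[v]) for u, v in g.edges],
        )
        assert len(enumerate_ffls(g)) == len(enumerate_ffls(h))


class TestClassifyFFL:
    def test_all_positive_is_coherent(self, toy_ffl_signed):
        t = classify_ffl(toy_ffl_signed, FFL("a", "b", "c"))
        assert t.coherent and t.type_id == 1

    def test_mixed_path_is_incoherent(self, toy_ffl):
        sg = SignedGraph(
            toy_ffl, {("a", "b"): +1, ("b", "c"): -1, ("a", "c"): +1}
        )
        assert not classify_ffl(sg, FFL("a", "b", "c")).coherent

    def test_exhaustive_sign_assignments_split_four_four(self, toy_ffl):
        f = FFL("a", "b", "c")
        seen = {}
        for s1, s2, s3 in itertools.product((+1, -1), repeat=3):
            sg = SignedGraph(
                toy_ffl, {("a", "b"): s1, ("b", "c"): s2, ("a", "c"): s3}
            )
            t = classify_ffl(sg, f)
            # coherence: direct edge sign equals the two-step path sign
            assert t.coherent == (s3 == s1 * s2)
            seen[t.type_id] = t.coherent
        assert sorted(seen) == list(range(1, 9))
        assert sum(seen.values()) == 4  # 4 coherent, 4 incoherent

    def test_unsigned_edge_raises(self, toy_ffl):
        sg = SignedGraph(toy_ffl, {("a", "b"): +1})
        with pytest.raises(KeyError):
            classify_ffl(sg, FFL("a", "b", "c"))


def canonical_form(edges, nodes):
    nodes = sorted(set(nodes), key=str)
    idx = {x: i for i, x in enumerate(nodes)}
    n = len(nodes)
    e = [(idx[u], idx[v]) for u, v in edges]
    best = None
    for p in itertools.permutations(range(n)):
        m = [0] * (n * n)
        for u, v in e:
            m[p[u] * n + p[v]] = 1
        if best is None or tuple(m) < best:
            best = tuple(m)
    return best


class TestClusterTaxonomy:
    """Brute-force isomorphism partitions of overlapping FFL pairs."""

    def test_share_one_node_yields_six_classes(self):
        forms = set()
        for r1, r2 in itertools.product(range(3), repeat=2):
            a, b = ["a0", "a1", "a2"], ["b0", "b1", "b2"]
            a[r1] = b[r2] = "s"
            f1, f2 = FFL(*a), FFL(*b)
            forms.add(canonical_form(f1.edge_set | f2.edge_set,
                                     f1.node_set | f2.node_set))
        assert len(forms) == 6

    def test_share_edge_yields_six_classes(self):
        f1 = FFL("a", "b", "c")
        forms = set()
        for shared in f1.edge_set:
            for perm in itertools.permutations((*shared, "z")):
                f2 = FFL(*perm)
                if shared in f2.edge_set and f2 != f1:
                    forms.add(canonical_form(f1.edge_set | f2.edge_set,
                                             f1.node_set | f2.node_set))
        assert len(forms) == 6

    def test_three_node_digraphs_two_plus_one_classes(self):
        """All 3-node digraphs with >= 2 FFLs: exactly two isomorphism
        classes carry two FFLs and one class carries three."""
        possible = [(a, b) for a in "xyz" for b in "xyz" if a != b]
        by_count = {}
        for r in range(len(possible) + 1):
            for sub in itertools.combinations(possible, r):
                g = DirectedGraph("xyz", sub)
                k = len(enumerate_ffls(g))
                if k >= 2:
                    by_count.setdefault(k, set()).add(canonical_form(sub, "xyz"))
        assert len(by_count[2]) == 2
        assert len(by_count[3]) == 1


class TestEnumerateClusters:
    def test_disjoint_ffls_form_no_cluster(self):
        g = DirectedGraph(
            "abcdef",
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f")],
        )
        counts = enumerate_clusters(g)
        assert all(c == 0 for c in counts.values())

    def test_two_ffls_sharing_regulator(self):
        g = DirectedGraph(
            "svwxy",
            [("s", "v"), ("v", "w"), ("s", "w"),
             ("s", "x"), ("x", "y"), ("s", "y")],
        )
        counts = enumerate_clusters(g)
        assert sum(counts.values()) == 1
        (motif,) = [m for m, c in counts.items() if c]
        assert 1 <= motif <= 6

    def test_edge_sharing_pair_lands_in_7_to_12(self):
        # both FFLs contain the edge (a, b)
        g = DirectedGraph(
            "abcz",
            [("a", "b"), ("b", "c"), ("a", "c"), ("b", "z"), ("a", "z")],
        )
        counts = enumerate_clusters(g)
        assert sum(counts.values()) == 1
        (motif,) = [m for m, c in counts.items() if c]
        assert 7 <= motif <= 12

    def test_three_ffls_on_three_nodes_is_motif_15(self):
        g = DirectedGraph(
            "abc",
            [("a", "b"), ("a", "c"), ("b", "a"), ("b", "c"), ("c", "a")],
        )
        assert len(enumerate_ffls(g)) == 3
        counts = enumerate_clusters(g)
        assert counts[15] == 1
        assert sum(c for m, c in counts.items() if m != 15) == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_overlap_class_totals_match_pair_oracle(self, seed):
        """Counts per overlap class agree with direct pair counting on
        random graphs (motifs 1-6 <-> one shared node, 7-12 <-> shared
        edge, 13-15 <-> one 3-node set)."""
        g = make_fixture("random_small", seed=seed, n=6, p=0.4)
        ffls = enumerate_ffls(g)
        counts = enumerate_clusters(g)

        share1 = share_edge = other2 = 0
        for f1, f2 in itertools.combinations(ffls, 2):
            shared = f1.node_set & f2.node_set
            if len(shared) == 1:
                share1 += 1
            elif len(shared) == 2:
                if f1.edge_set & f2.edge_set:
                    share_edge += 1
                else:
                    other2 += 1
        by_set = {}
        for f in ffls:
            by_set.setdefault(f.node_set, []).append(f)
        two_sets = sum(1 for m in by_set.values() if len(m) == 2)
        three_sets = sum(1 for m in by_set.values() if len(m) == 3)
        many_sets = sum(1 for m in by_set.values() if len(m) > 3)

        assert sum(counts[m] for m in range(1, 7)) == share1
        assert sum(counts[m] for m in range(7, 13)) == share_edge
        assert counts[13] + counts[14] == two_sets
        assert counts[15] == three_sets
        assert counts[0] == other2 + many_sets


def brute_force_cycles(g: DirectedGraph, max_len: int):
    """Exhaustive simple-path DFS oracle, canonical rotations."""
    found = set()

    def dfs(start, node, path):
        for nxt in g.successors(node):
            if nxt == start and len(path) <= max_len:
                found.add(tuple(path))
            elif nxt not in path and nxt > start and len(path) < max_len:
                dfs(start, nxt, path + [nxt])

    for v in g.nodes:
        dfs(v, v, [v])
    return found


class TestEnumerateFBLs:
    def test_self_loop_is_length_one(self):
        g = DirectedGraph("ab", [("a", "a"), ("a", "b")])
        fbls = enumerate_fbls(g)
        assert [f.length for f in fbls] == [1]

    def test_two_cycle(self):
        g = DirectedGraph("ab", [("a", "b"), ("b", "a")])
        (f,) = enumerate_fbls(g)
        assert f.length == 2 and f.nodes == ("a", "b")

    def test_max_len_bounds_search(self):
        g = make_fixture("toy_cycle", length=5)
        assert enumerate_fbls(g, max_len=4) == []
        assert len(enumerate_fbls(g, max_len=5)) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dfs_oracle(self, seed):
        g = make_fixture("random_small", seed=seed, n=8, p=0.25)
        got = {f.nodes for f in enumerate_fbls(g, max_len=6)}
        assert got == brute_force_cycles(g, 6)


class TestPathSign:
    def test_all_positive(self, toy_ffl_signed):
        assert path_sign(toy_ffl_signed, ["a", "b", "c"]) == +1

    def test_one_negative_edge(self, toy_ffl):
        sg = SignedGraph(toy_ffl, {("a", "b"): +1, ("b", "c"): -1, ("a", "c"): +1})
        assert path_sign(sg, ["a", "b", "c"]) == -1

    def test_concatenation_multiplies(self):
        sg = random_signed(n=7, p=0.9, seed=2)
        nodes = sg.graph.nodes
        # any 2-edge concatenation through existing edges
        checked = 0
        for a in nodes:
            for b in sg.graph.successors(a):
                for c in sg.graph.successors(b):
                    assert path_sign(sg, [a, b, c]) == (
                        path_sign(sg, [a, b]) * path_sign(sg, [b, c])
                    )
                    checked += 1
        assert checked > 0

    def test_missing_edge_raises(self, toy_ffl_signed):
        with pytest.raises(KeyError):
            path_sign(toy_ffl_signed, ["c", "a"])


class TestFBLSignDuality:
    @pytest.mark.parametrize("seed", range(6))
    def test_negating_all_signs_flips_odd_cycles(self, seed):
        sg = random_signed(n=7, p=0.3, seed=seed)
        neg = SignedGraph(sg.graph, {e: -s for e, s in sg.signs.items()})
        for f in enumerate_fbls(sg.graph, max_len=6):
            s0, s1 = fbl_sign(sg, f), fbl_sign(neg, f)
            if f.length % 2:
                assert s1 == -s0
            else:
                assert s1 == s0


class TestCensusReport:
    def test_all_positive_ffl_concentrates_on_type_one(self, toy_ffl_signed):
        rep = census_report(toy_ffl_signed)
        assert rep.ffl_type_freq() == (1.0, 0, 0, 0, 0, 0, 0, 0)

    def test_acyclic_graph_has_empty_fbl_bins(self, toy_ffl_signed):
        rep = census_report(toy_ffl_signed)
        assert all(v is None for v in rep.fbl_positive_fraction.values())
        assert rep.n_fbls == 0

    def test_partial_signing_rejected(self, toy_ffl):
        with pytest.raises(ValueError, match="totally signed"):
            census_report(SignedGraph(toy_ffl, {("a", "b"): 1}))

    def test_pos_input_fraction_by_in_degree(self, toy_ffl):
        sg = SignedGraph(toy_ffl, {("a", "b"): +1, ("b", "c"): -1, ("a", "c"): +1})
        rep = census_report(sg)
        # b has in-degree 1 (activator); c has in-degree 2 (one of each)
        assert rep.pos_input_fraction == {1: 1.0, 2: 0.5}
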