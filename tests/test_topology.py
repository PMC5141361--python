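"""Permutation pathway tests, path scoring, meta-pathway and final selection."""

import itertools

import numpy as np
import pytest

from mirpathnet import (
    PathwayGraph,
    adjust_pathway_qvalues,
    analyze_pathway,
    clique_tests,
    enumerate_clique_paths,
    final_path_selection,
    pathway_tests,
    score_path,
    select_meta_pathway,
)
from mirpathnet.chordal import CliqueTree
from mirpathnet.pathways import PathwayEdge
from mirpathnet.topology import PathResult, PathwayTest, scored_paths_for_pathway

from conftest import make_matrix


def chain_pathway(genes):
    nodes = {g: "gene" for g in genes}
    edges = [PathwayEdge(a, b, True, "activation") for a, b in zip(genes, genes[1:])]
    return PathwayGraph("pw", "chain", nodes, edges)


def two_class_matrix(rng, genes, n_per_class=20, shift=None):
    n = 2 * n_per_class
    vals = rng.standard_normal((len(genes), n))
    if shift:
        for g, delta in shift.items():
            vals[genes.index(g), :n_per_class] += delta
    samples = [f"s{i:02d}" for i in range(n)]
    conds = ["A"] * n_per_class + ["B"] * n_per_class
    return make_matrix(vals, genes, samples, conds)


class TestPermutationTests:
    def test_null_p_values_roughly_uniform(self, rng):
        genes = [f"g{i}" for i in range(6)]
        pw = chain_pathway(genes)
        ps = []
        for rep in range(40):
            mat = two_class_matrix(rng, genes)
            t = pathway_tests(mat, pw, "A", "B", n_perm=99, seed=rep)
            ps.extend([t.p_mean, t.p_var])
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.1).mean() < 0.25

    def test_planted_shift_detected(self, rng):
        genes = [f"g{i}" for i in range(6)]
        pw = chain_pathway(genes)
        hits = 0
        for rep in range(10):
            mat = two_class_matrix(rng, genes, n_per_class=30,
                                   shift={g: 2.0 for g in genes})
            t = pathway_tests(mat, pw, "A", "B", n_perm=199, seed=rep)
            hits += t.p_mean <= 0.01
        assert hits >= 9

    def test_p_bounded_below_by_add_one(self, rng):
        genes = [f"g{i}" for i in range(4)]
        mat = two_class_matrix(rng, genes, n_per_class=25,
                               shift={g: 3.0 for g in genes})
        t = pathway_tests(mat, chain_pathway(genes), "A", "B", n_perm=49, seed=0)
        assert t.p_mean >= 1 / 50 and t.p_var >= 1 / 50

    def test_deterministic_given_seed(self, rng):
        genes = [f"g{i}" for i in range(5)]
        mat = two_class_matrix(rng, genes)
        pw = chain_pathway(genes)
        t1 = pathway_tests(mat, pw, "A", "B", n_perm=99, seed=11)
        t2 = pathway_tests(mat, pw, "A", "B", n_perm=99, seed=11)
        assert (t1.p_mean, t1.p_var) == (t2.p_mean, t2.p_var)

    def test_absent_nodes_dropped_with_warning(self, rng):
        genes = [f"g{i}" for i in range(5)]
        mat = two_class_matrix(rng, genes[:4])
        with pytest.warns(UserWarning, match="absent"):
            t = pathway_tests(mat, chain_pathway(genes), "A", "B", n_perm=49, seed=0)
        assert 0 < t.p_mean <= 1


class TestCliqueTests:
    def test_single_clique_matches_pathway_test(self, rng):
        genes = [f"g{i}" for i in range(3)]
        pw = PathwayGraph("pw", "triangle", {g: "gene" for g in genes},
                          [PathwayEdge("g0", "g1", True, "activation"),
                           PathwayEdge("g1", "g2", True, "activation"),
                           PathwayEdge("g0", "g2", True, "activation")])
        mat = two_class_matrix(rng, genes, shift={"g0": 1.0})
        t = pathway_tests(mat, pw, "A", "B", n_perm=99, seed=5)
        ct = CliqueTree([frozenset(genes)], [], [])
        ((pm, pv),) = clique_tests(mat, ct, "A", "B", n_perm=99, seed=5)
        assert (pm, pv) == (t.p_mean, t.p_var)

    def test_signal_localizes_to_shifted_clique(self, rng):
        genes = [f"g{i}" for i in range(8)]
        shifted = {g: 1.5 for g in genes[:2]}
        pms_hot, pms_cold = [], []
        for rep in range(10):
            mat = two_class_matrix(rng, genes, n_per_class=30, shift=shifted)
            ct = CliqueTree(
                [frozenset(genes[:2]), frozenset(genes[6:])],
                [(0, 1)], [frozenset()],
            )
            (hot, cold) = clique_tests(mat, ct, "A", "B", n_perm=99, seed=rep)
            pms_hot.append(hot[0])
            pms_cold.append(cold[0])
        assert np.median(pms_hot) <= 0.02
        assert 0.2 < np.mean(pms_cold) < 0.8


class TestQValueAdjustment:
    def test_single_pathway_q_equals_p(self):
        (t,) = adjust_pathway_qvalues([PathwayTest("p", 0.03, 0.5)])
        assert t.q_mean == pytest.approx(0.03) and t.q_var == pytest.approx(0.5)
        assert t.significant

    def test_boundary_q_exactly_threshold_is_significant(self):
        (t,) = adjust_pathway_qvalues([PathwayTest("p", 0.1, 0.9)], q_max=0.1)
        assert t.q_mean == pytest.approx(0.1)
        assert t.significant  # non-strict "<="

    def test_families_adjusted_separately_against_oracle(self, rng):
        from test_targets import naive_bh

        tests = [PathwayTest(f"p{i}", float(p), float(v))
                 for i, (p, v) in enumerate(zip(rng.uniform(size=8),
                                                rng.uniform(size=8)))]
        out = adjust_pathway_qvalues(tests)
        assert np.allclose([t.q_mean for t in out], naive_bh([t.p_mean for t in tests]))
        assert np.allclose([t.q_var for t in out], naive_bh([t.p_var for t in tests]))

    def test_and_mode_stricter(self):
        tests = [PathwayTest("a", 0.01, 0.9), PathwayTest("b", 0.5, 0.6)]
        either = adjust_pathway_qvalues(tests, mode="either")
        both = adjust_pathway_qvalues(tests, mode="both")
        assert either[0].significant and not both[0].significant


def star_tree():
    """Star-shaped clique tree: center clique 0, leaves 1..3."""
    cliques = [frozenset({"c", f"l{i}"}) for i in range(3)]
    cliques.insert(0, frozenset({"c"}))
    return CliqueTree(
        cliques,
        [(0, 1), (0, 2), (0, 3)],
        [frozenset({"c"})] * 3,
    )


class TestPathEnumeration:
    def test_path_shaped_tree_single_path(self):
        ct = CliqueTree([frozenset("ab"), frozenset("bc"), frozenset("cd")],
                        [(0, 1), (1, 2)], [frozenset("b"), frozenset("c")])
        paths = enumerate_clique_paths(ct)
        assert len(paths) == 1 and paths[0].clique_indices == (0, 1, 2)

    def test_star_gives_leaf_pairs(self):
        paths = enumerate_clique_paths(star_tree())
        assert len(paths) == 3  # 3 choose 2 leaf pairs

    def test_single_clique_trivial_path(self):
        ct = CliqueTree([frozenset("xyz")], [], [])
        (p,) = enumerate_clique_paths(ct)
        assert p.clique_indices == (0,) and p.nodes == frozenset("xyz")

    @pytest.mark.parametrize("seed", range(6))
    def test_count_matches_brute_force_on_random_trees(self, seed):
        local = np.random.default_rng(seed)
        k = int(local.integers(2, 9))
        edges = [(int(local.integers(i)), i) for i in range(1, k)]
        cliques = [frozenset({f"v{i}", "shared"}) for i in range(k)]
        ct = CliqueTree(cliques, edges, [frozenset({"shared"})] * len(edges))
        paths = enumerate_clique_paths(ct)
        deg = {i: 0 for i in range(k)}
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        leaves = [i for i in range(k) if deg[i] <= 1]
        expected = len(list(itertools.combinations(leaves, 2))) if k > 1 else 1
        assert len(paths) == expected


class TestScoring:
    def test_all_p_one_scores_zero(self):
        p = PathResult((0, 1), frozenset("ab"))
        assert score_path(p, [(1.0, 1.0), (1.0, 1.0)]) == 0.0

    def test_uniform_p_001_scores_two(self):
        p = PathResult((0, 1, 2), frozenset("abc"))
        assert score_path(p, [(0.01, 0.5)] * 3) == pytest.approx(2.0)

    def test_mixed_p_matches_hand_mean(self):
        p = PathResult((0, 1), frozenset("ab"))
        expected = np.mean([-np.log10(0.05), -np.log10(0.2)])
        assert score_path(p, [(0.05, 0.9), (0.5, 0.2)]) == pytest.approx(expected)


def tiny_graph(pid, genes):
    nodes = {g: "gene" for g in genes}
    edges = [PathwayEdge(a, b, True, "activation") for a, b in zip(genes, genes[1:])]
    return PathwayGraph(pid, pid, nodes, edges)


class TestMetaPathway:
    def _scored(self, pid, label_nodes, score):
        return PathResult(tuple(range(len(label_nodes))), frozenset(label_nodes),
                          score=score, pathway_id=pid)

    def test_fewer_than_k_merges_all(self):
        g = tiny_graph("p1", ["a", "b", "c"])
        paths = [self._scored("p1", ["a", "b"], 2.0), self._scored("p1", ["b", "c"], 1.0)]
        meta = select_meta_pathway(paths, {"p1": g}, k=10)
        assert set(meta.nodes) == {"a", "b", "c"}

    def test_duplicate_paths_idempotent_union(self):
        g = tiny_graph("p1", ["a", "b"])
        paths = [self._scored("p1", ["a", "b"], 2.0)] * 2
        meta = select_meta_pathway(paths, {"p1": g}, k=10)
        assert set(meta.nodes) == {"a", "b"} and len(meta.edges) == 1

    def test_top_k_cut_and_induced_edges(self):
        g1 = tiny_graph("p1", ["a", "b", "c"])
        g2 = tiny_graph("p2", ["x", "y"])
        paths = [self._scored("p1", ["a", "b", "c"], 3.0),
                 self._scored("p2", ["x", "y"], 1.0)]
        meta = select_meta_pathway(paths, {"p1": g1, "p2": g2}, k=1)
        assert set(meta.nodes) == {"a", "b", "c"}
        assert {(e.src, e.dst) for e in meta.edges} == {("a", "b"), ("b", "c")}


class TestFinalSelection:
    def test_upper_quartile_with_ties_kept(self, rng):
        genes = [f"g{i}" for i in range(7)]
        pw = chain_pathway(genes)
        mat = two_class_matrix(rng, genes, n_per_class=25,
                               shift={g: 2.0 for g in genes[:3]})
        out = final_path_selection(pw, mat, "A", "B", n_perm=99, seed=3)
        assert out, "at least one path must be selected"
        full = scored_paths_for_pathway(
            *_reanalyze(pw, mat), pathway_id="pw")
        scores = [p.score for p in full]
        threshold = np.quantile(scores, 0.75)
        assert {p.label for p in out} == {p.label for p in full if p.score >= threshold}

    def test_planted_path_recovered_from_bundle(self, default_pipeline_result, default_bundle):
        truth_nodes = set(default_bundle.truth.planted_path_nodes["pw1"])
        for cr in default_pipeline_result.comparisons.values():
            found = set().union(*(p.nodes for p in cr.final_paths))
            assert truth_nodes <= found


def _reanalyze(pw, mat):
    from mirpathnet.topology import _decompose, clique_tests as _ct

    nodes, ct = _decompose(pw, mat)
    results = _ct(mat, ct, "A", "B", n_perm=99, seed=3, nodes=nodes)
    return ct, results
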