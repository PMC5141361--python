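"""TF-miRNA-gene circuit enumeration, filtering and coherence classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirpathnet import (
    Circuit,
    PredictedTargets,
    TFCatalog,
    classify_ffl,
    enumerate_candidates,
    link_to_network,
    score_and_filter,
)

from conftest import make_matrix


def catalog(tf_mirna_rows, tf_gene_rows):
    return TFCatalog(
        pd.DataFrame(tf_mirna_rows, columns=["tf_id", "mirna_id", "source"]),
        pd.DataFrame(tf_gene_rows, columns=["tf_id", "target_gene_id", "source"]),
    )


def predictions(pairs):
    return PredictedTargets(pd.DataFrame(
        [(m, g, 0.9) for m, g in pairs], columns=["mirna_id", "gene_id", "score"]))


class TestEnumeration:
    def test_empty_catalogs(self):
        cands = enumerate_candidates(catalog([], []), predictions([("m", "g")]),
                                     {"g"}, {"m"})
        assert cands == []

    def test_single_tf_master_candidate(self):
        cands = enumerate_candidates(
            catalog([("T", "m", "s")], [("T", "g", "s")]),
            predictions([("m", "g")]), {"T", "g"}, {"m"})
        assert cands == [Circuit("tf_master", "T", "m", "g")]

    def test_mirna_master_requires_both_predictions(self):
        cat = catalog([], [("T", "g", "s")])
        full = enumerate_candidates(cat, predictions([("m", "T"), ("m", "g")]),
                                    {"T", "g"}, {"m"})
        assert full == [Circuit("mirna_master", "T", "m", "g")]
        partial = enumerate_candidates(cat, predictions([("m", "T")]),
                                       {"T", "g"}, {"m"})
        assert partial == []

    def test_members_must_be_measured(self):
        cands = enumerate_candidates(
            catalog([("T", "m", "s")], [("T", "g", "s")]),
            predictions([("m", "g")]), {"T"}, {"m"})  # gene g unmeasured
        assert cands == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_triple_enumeration(self, seed):
        local = np.random.default_rng(seed)
        tfs = [f"T{i}" for i in range(3)]
        mirnas = [f"m{i}" for i in range(3)]
        genes = [f"g{i}" for i in range(4)] + tfs
        tm = [(t, m, "s") for t in tfs for m in mirnas if local.random() < 0.4]
        tg = [(t, g, "s") for t in tfs for g in genes if g != t and local.random() < 0.4]
        pr = [(m, g) for m in mirnas for g in genes if local.random() < 0.4]
        cands = enumerate_candidates(catalog(tm, tg), predictions(pr),
                                     set(genes), set(mirnas))
        preds = set(pr)
        tms = {(a, b) for a, b, _ in tm}
        tgs = {(a, b) for a, b, _ in tg}
        expected = set()
        for t, m, g in itertools.product(tfs, mirnas, genes):
            if g == t:
                continue
            if (t, m) in tms and (t, g) in tgs and (m, g) in preds:
                expected.add(("tf_master", t, m, g))
            if (m, t) in preds and (m, g) in preds and (t, g) in tgs:
                expected.add(("mirna_master", t, m, g))
        got = {(c.topology, c.tf_id, c.mirna_id, c.gene_id) for c in cands}
        assert got == expected
        assert len(cands) == len(got)  # no duplicates

    def test_row_order_invariance(self):
        tm = [("T", "m", "s"), ("U", "m", "s")]
        tg = [("T", "g", "s"), ("U", "g", "s")]
        pr = [("m", "g")]
        a = enumerate_candidates(catalog(tm, tg), predictions(pr), {"T", "U", "g"}, {"m"})
        b = enumerate_candidates(catalog(tm[::-1], tg[::-1]), predictions(pr),
                                 {"T", "U", "g"}, {"m"})
        assert a == b


def correlated_triplet_matrices(rng, s_tf=1.0, s_m=-1.0, s_g=1.0, loading=0.9, n=50):
    t = rng.standard_normal(n)
    resid = np.sqrt(1 - loading**2)
    tf = s_tf * loading * t + resid * rng.standard_normal(n)
    m = s_m * loading * t + resid * rng.standard_normal(n)
    g = s_g * loading * t + resid * rng.standard_normal(n)
    samples = [f"s{i}" for i in range(n)]
    conds = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    gene_mat = make_matrix(np.vstack([tf, g]), ["TF", "G"], samples, conds)
    mirna_mat = make_matrix(m[None, :], ["M"], samples, conds, "mirna")
    return mirna_mat, gene_mat


class TestScoreAndFilter:
    def test_strong_circuit_retained_and_classified(self, rng):
        mirna_mat, gene_mat = correlated_triplet_matrices(rng)
        (c,) = score_and_filter([Circuit("tf_master", "TF", "M", "G")],
                                mirna_mat, gene_mat)
        assert c.r_tf_mirna < -0.5 and c.r_tf_gene > 0.5 and c.r_mirna_gene < -0.5
        assert c.coherence == "coherent"

    def test_boundary_abs_r_exactly_threshold_retained(self, rng):
        mirna_mat, gene_mat = correlated_triplet_matrices(rng, loading=0.8)
        (scored,) = score_and_filter([Circuit("tf_master", "TF", "M", "G")],
                                     mirna_mat, gene_mat, min_abs_r=0.0)
        weakest = min(abs(scored.r_tf_mirna), abs(scored.r_tf_gene),
                      abs(scored.r_mirna_gene))
        # threshold set exactly at the weakest edge: non-strict, retained
        assert score_and_filter([Circuit("tf_master", "TF", "M", "G")],
                                mirna_mat, gene_mat, min_abs_r=weakest)
        # infinitesimally above: dropped
        assert not score_and_filter([Circuit("tf_master", "TF", "M", "G")],
                                    mirna_mat, gene_mat,
                                    min_abs_r=np.nextafter(weakest, 1))

    def test_filter_monotone_in_threshold(self, rng):
        mirna_mat, gene_mat = correlated_triplet_matrices(rng, loading=0.75)
        cand = [Circuit("tf_master", "TF", "M", "G")]
        kept = [len(score_and_filter(cand, mirna_mat, gene_mat, min_abs_r=x))
                for x in (0.0, 0.3, 0.6, 0.9, 0.99)]
        assert kept == sorted(kept, reverse=True)


class TestClassifyFFL:
    @pytest.mark.parametrize("s_tm,s_tg,s_mg", list(itertools.product([1, -1], repeat=3)))
    def test_tf_master_truth_table(self, s_tm, s_tg, s_mg):
        c = Circuit("tf_master", "T", "m", "g",
                    r_tf_mirna=0.7 * s_tm, r_tf_gene=0.7 * s_tg,
                    r_mirna_gene=0.7 * s_mg)
        # direct TF->gene sign s_tg; indirect = s_tm * (-1) via miRNA repression
        expected = "coherent" if s_tg == -s_tm else "incoherent"
        assert classify_ffl(c) == expected

    @pytest.mark.parametrize("s_tm,s_tg,s_mg", list(itertools.product([1, -1], repeat=3)))
    def test_mirna_master_truth_table(self, s_tm, s_tg, s_mg):
        c = Circuit("mirna_master", "T", "m", "g",
                    r_tf_mirna=0.7 * s_tm, r_tf_gene=0.7 * s_tg,
                    r_mirna_gene=0.7 * s_mg)
        # direct miRNA->gene is repressive (-); indirect = (-1) * s_tg
        expected = "coherent" if s_tg == 1 else "incoherent"
        assert classify_ffl(c) == expected

    def test_zero_correlation_undefined(self):
        c = Circuit("tf_master", "T", "m", "g", 0.0, 0.5, -0.5)
        with pytest.raises(ValueError, match="undefined"):
            classify_ffl(c)


class TestLinkToNetwork:
    def test_disjoint_dropped_shared_mirna_kept_empty_ok(self):
        c1 = Circuit("tf_master", "T1", "m1", "g1")
        c2 = Circuit("tf_master", "T2", "m2", "g2")
        assert link_to_network([c1, c2], {"m2", "x"}) == [c2]
        assert link_to_network([c1], {"zzz"}) == []
        assert link_to_network([], {"a"}) == []
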