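"""Expression matrix loading, filtering, fold changes and clustering."""

import numpy as np
import pandas as pd
import pytest

from mirpathnet import (
    entropy_filter,
    filter_features,
    hcluster_samples,
    log2_fold_change,
    mean_expression_filter,
    read_expression_matrix,
    shannon_entropy_bits,
    write_expression_matrix,
)
from mirpathnet.expression import ExpressionMatrix, read_sample_annotation

from conftest import make_annotation, make_matrix


class TestIO:
    def test_read_well_formed(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "feature_id\ts1\ts2\ng1\t1.5\t2.0\ng2\t0.0\t-1.0\ng3\t3.25\t4.5\n"
        )
        (tmp_path / "a.tsv").write_text("sample_id\tcondition\ns1\tA\ns2\tB\n")
        mat = read_expression_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv", "gene")
        assert mat.n_features == 3 and mat.n_samples == 2
        assert mat.sample_ids == ["s1", "s2"]  # file order preserved
        assert mat.values.loc["g3", "s2"] == 4.5

    def test_unannotated_sample_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("feature_id\ts1\ts2\ng1\t1\t2\n")
        (tmp_path / "a.tsv").write_text("sample_id\tcondition\ns1\tA\n")
        with pytest.raises(ValueError, match="without annotation"):
            read_expression_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv", "gene")

    def test_non_numeric_cell_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("feature_id\ts1\ng1\tNA?\n")
        (tmp_path / "a.tsv").write_text("sample_id\tcondition\ns1\tA\n")
        with pytest.raises(ValueError):
            read_expression_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv", "gene")

    def test_round_trip_bitwise(self, tmp_path, rng):
        vals = rng.normal(8, 2, size=(7, 4))
        mat = make_matrix(vals, [f"g{i}" for i in range(7)], [f"s{i}" for i in range(4)],
                          ["A", "A", "B", "B"])
        write_expression_matrix(mat, tmp_path / "m.tsv")
        ann = pd.DataFrame({"sample_id": mat.sample_ids,
                            "condition": ["A", "A", "B", "B"]})
        ann.to_csv(tmp_path / "a.tsv", sep="\t", index=False)
        back = read_expression_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv", "gene")
        assert (back.values.to_numpy() == mat.values.to_numpy()).all()


class TestMeanFilter:
    def test_quantile_cutoff(self):
        # means 1,2,3,4; 25% linear-interpolation quantile is 1.75
        mat = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0]]),
                          list("abcd"), ["s1"], ["A"])
        out = mean_expression_filter(mat, 0.25)
        assert out.feature_ids == ["b", "c", "d"]

    def test_zero_fraction_identity(self, rng):
        mat = make_matrix(rng.normal(size=(5, 3)), list("abcde"),
                          ["s1", "s2", "s3"], ["A", "A", "B"])
        assert mean_expression_filter(mat, 0.0).feature_ids == mat.feature_ids

    def test_tied_means_none_removed(self):
        mat = make_matrix(np.full((4, 2), 7.0), list("abcd"), ["s1", "s2"], ["A", "B"])
        assert mean_expression_filter(mat, 0.25).n_features == 4

    def test_survivor_order_preserved(self, rng):
        vals = rng.normal(8, 3, size=(20, 5))
        feats = [f"g{i:02d}" for i in range(20)][::-1]  # deliberately unsorted
        mat = make_matrix(vals, feats, [f"s{i}" for i in range(5)],
                          ["A"] * 3 + ["B"] * 2)
        out = mean_expression_filter(mat, 0.25)
        kept = set(out.feature_ids)
        assert out.feature_ids == [f for f in feats if f in kept]


class TestEntropy:
    def test_constant_profile_zero(self):
        assert shannon_entropy_bits(np.full(30, 5.0)) == 0.0

    def test_uniform_over_eight_bins_is_three_bits(self):
        # 80 values, 10 per occupied bin (bins 0-6 and 9 of 10 over [0,10])
        vals = ([0.0] + [0.5] * 9 + sum(([b + 0.5] * 10 for b in range(1, 7)), [])
                + [9.5] * 9 + [10.0])
        assert len(vals) == 80
        assert shannon_entropy_bits(np.array(vals), n_bins=10) == pytest.approx(3.0)

    def test_matches_histogram_oracle(self):
        profile = np.array([0, 0, 0, 1, 1, 9, 9, 10, 10, 10], dtype=float)
        counts, _ = np.histogram(profile, bins=10, range=(0, 10))
        p = counts[counts > 0] / profile.size
        expected = -(p * np.log2(p)).sum()
        assert shannon_entropy_bits(profile, 10) == pytest.approx(expected)
        assert expected == pytest.approx(1.4854752972273344)

    def test_bounds_and_affine_invariance(self, rng):
        for _ in range(20):
            x = rng.normal(size=40)
            h = shannon_entropy_bits(x, 10)
            assert 0 <= h <= np.log2(10)
            assert shannon_entropy_bits(3.7 * x + 11.0, 10) == pytest.approx(h)


class TestEntropyFilter:
    def test_constant_features_all_removed(self):
        mat = make_matrix(np.ones((3, 10)), list("abc"),
                          [f"s{i}" for i in range(10)], ["A"] * 5 + ["B"] * 5)
        assert entropy_filter(mat).n_features == 0

    def test_zero_threshold_identity(self, rng):
        mat = make_matrix(rng.normal(size=(4, 10)), list("abcd"),
                          [f"s{i}" for i in range(10)], ["A"] * 5 + ["B"] * 5)
        assert entropy_filter(mat, threshold=0.0).feature_ids == mat.feature_ids

    def test_survivors_match_per_feature_oracle(self, rng):
        vals = np.vstack([rng.normal(size=20), np.full(20, 3.0),
                          rng.normal(size=20) * 5, np.repeat([1.0, 2.0], 10)])
        mat = make_matrix(vals, list("abcd"), [f"s{i}" for i in range(20)],
                          ["A"] * 10 + ["B"] * 10)
        out = entropy_filter(mat, threshold=1.4, n_bins=10)
        expected = [f for f, row in zip(mat.feature_ids, vals)
                    if shannon_entropy_bits(row, 10) >= 1.4]
        assert out.feature_ids == expected

    def test_union_composition_order_insensitive(self, rng):
        vals = rng.normal(6, 2, size=(30, 15))
        vals[5] = 2.0  # weak and constant
        vals[6] = np.linspace(10, 10.01, 15)  # strong but low-entropy-ish range
        mat = make_matrix(vals, [f"g{i}" for i in range(30)],
                          [f"s{i}" for i in range(15)], ["A"] * 8 + ["B"] * 7)
        combined = filter_features(mat, 0.25, 1.4)
        means = vals.mean(axis=1)
        cutoff = np.quantile(means, 0.25)
        expected = [
            f for f, m, row in zip(mat.feature_ids, means, vals)
            if m >= cutoff and shannon_entropy_bits(row, 10) >= 1.4
        ]
        assert combined.feature_ids == expected


class TestFoldChange:
    def test_identical_groups_zero(self):
        vals = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (1, 2))
        mat = make_matrix(vals[:, :4], list("ab"), [f"s{i}" for i in range(4)],
                          ["A", "A", "B", "B"])
        mat.values.loc[:, ["s2", "s3"]] = mat.values[["s0", "s1"]].to_numpy()
        fc = log2_fold_change(mat, "A", "B")
        assert np.allclose(fc, 0)

    def test_exact_shift_recovered(self, rng):
        base = rng.normal(8, 1, size=(5, 3))
        vals = np.hstack([base + 1.25, base])
        mat = make_matrix(vals, [f"g{i}" for i in range(5)],
                          [f"s{i}" for i in range(6)], ["A"] * 3 + ["B"] * 3)
        assert np.allclose(log2_fold_change(mat, "A", "B"), 1.25)

    def test_matches_mean_difference_oracle_and_antisymmetry(self, rng):
        vals = rng.normal(size=(5, 6))
        mat = make_matrix(vals, [f"g{i}" for i in range(5)],
                          [f"s{i}" for i in range(6)], ["A"] * 2 + ["B"] * 4)
        fc = log2_fold_change(mat, "A", "B")
        oracle = vals[:, :2].mean(axis=1) - vals[:, 2:].mean(axis=1)
        assert np.allclose(fc, oracle)
        assert np.allclose(log2_fold_change(mat, "B", "A"), -fc)

    def test_stratified_restricts_case_group(self, rng):
        vals = rng.normal(size=(3, 6))
        ann = make_annotation([f"s{i}" for i in range(6)],
                              ["A"] * 4 + ["B"] * 2,
                              ["m1", "m1", "m2", "m2", "none", "none"])
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=list("xyz"), columns=[f"s{i}" for i in range(6)]),
            "gene", ann)
        fc = log2_fold_change(mat, "A", "B", stratify_by="m1")
        oracle = vals[:, :2].mean(axis=1) - vals[:, 4:].mean(axis=1)
        assert np.allclose(fc, oracle)
        with pytest.raises(ValueError, match="empty stratum"):
            log2_fold_change(mat, "A", "B", stratify_by="nope")


class TestClustering:
    def test_duplicate_samples_merge_at_zero(self):
        vals = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]])
        mat = make_matrix(vals, ["g1", "g2"], ["s1", "s2", "s3"], ["A", "A", "B"])
        res = hcluster_samples(mat, ["g1", "g2"])
        assert res["linkage"][0, 2] == 0.0

    def test_complete_linkage_hand_case(self):
        # 1-D samples at 0, 1, 10: merge (0,1) at height 1, then at height 10
        vals = np.array([[0.0, 1.0, 10.0]])
        mat = make_matrix(vals, ["g1"], ["s1", "s2", "s3"], ["A", "A", "B"])
        z = hcluster_samples(mat, ["g1"])["linkage"]
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx(10.0)

    def test_sample_order_invariance_and_monotone_heights(self, rng):
        vals = rng.normal(size=(4, 6))
        samples = [f"s{i}" for i in range(6)]
        mat = make_matrix(vals, list("abcd"), samples, ["A"] * 3 + ["B"] * 3)
        perm = [3, 1, 5, 0, 2, 4]
        mat2 = make_matrix(vals[:, perm], list("abcd"), [samples[i] for i in perm],
                           [(["A"] * 3 + ["B"] * 3)[i] for i in perm])
        z1 = hcluster_samples(mat, list("abcd"))["linkage"]
        z2 = hcluster_samples(mat2, list("abcd"))["linkage"]
        assert np.allclose(z1[:, 2], z2[:, 2])
        assert (np.diff(z1[:, 2]) >= -1e-12).all()
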