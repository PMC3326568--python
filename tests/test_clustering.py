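import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_centroid_merges
from tilsig.clustering import (
    LinkageTree,
    centroid_linkage,
    classify_cases,
    cut_tree,
    detect_outliers,
    label_and_merge,
)
from tilsig.io import z_normalize_rows
from tilsig.signature import CANONICAL_SIGNATURE
from tilsig.simulate import SimulationConfig, generate_cohort


def _ids(n):
    return [f"s{i}" for i in range(n)]


class TestCentroidLinkage:
    def test_merge_list_well_formed(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((12, 3))
        tree = centroid_linkage(pts, _ids(12))
        assert tree.n_leaves == 12
        assert len(tree.merges) == 11
        assert tree.merges[-1][3] == 12  # final cluster holds everything
        seen = set(range(12))
        for step, (a, b, h, size) in enumerate(tree.merges):
            assert a in seen and b in seen and a != b
            assert h >= 0
            seen -= {a, b}
            seen.add(12 + step)

    def test_two_separated_blobs_split_first(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.standard_normal((5, 2)) * 0.1, rng.standard_normal((5, 2)) * 0.1 + 50]
        )
        tree = centroid_linkage(pts, _ids(10))
        cut = cut_tree(tree, 2)
        assert cut.iloc[:5].nunique() == 1
        assert cut.iloc[5:].nunique() == 1
        assert cut.iloc[0] != cut.iloc[9]

    def test_tie_broken_by_smallest_node_pair(self):
        # unit square: all four edges tie at distance 1
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        tree = centroid_linkage(pts, _ids(4))
        assert tree.merges[0][:2] == (0, 1)

    def test_height_inversion_tolerated_and_cut_still_valid(self):
        # near-equilateral triangle: the merged centroid sits closer to the
        # third point than the first merge height — a classic inversion
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.87]])
        tree = centroid_linkage(pts, _ids(3))
        assert tree.merges[1][2] < tree.merges[0][2]
        cut = cut_tree(tree, 2)
        assert sorted(cut.value_counts().tolist()) == [1, 2]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        pts = rng.standard_normal((n, int(rng.integers(1, 4))))
        tree = centroid_linkage(pts, _ids(n))
        expected = brute_force_centroid_merges(pts)
        for got, want in zip(tree.merges, expected):
            assert got[:2] == want[:2]
            assert got[2] == pytest.approx(want[2], abs=1e-9)
            assert got[3] == want[3]

    def test_one_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            centroid_linkage(np.array([[0.0]]), _ids(1))

    def test_nan_points_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            centroid_linkage(np.array([[0.0], [np.nan]]), _ids(2))

    def test_tree_merge_count_validated(self):
        with pytest.raises(ValueError, match="merges"):
            LinkageTree(leaf_ids=("a", "b", "c"), merges=((0, 1, 1.0, 2),))


class TestCutTree:
    @pytest.fixture()
    def tree(self):
        rng = np.random.default_rng(2)
        return centroid_linkage(rng.standard_normal((9, 2)), _ids(9))

    def test_extreme_cuts(self, tree):
        assert cut_tree(tree, 1).nunique() == 1
        assert cut_tree(tree, 9).nunique() == 9

    def test_cuts_are_nested_refinements(self, tree):
        for k in range(1, 9):
            coarse = cut_tree(tree, k)
            fine = cut_tree(tree, k + 1)
            # every fine cluster must sit inside exactly one coarse cluster
            mapping = pd.DataFrame({"f": fine, "c": coarse})
            assert (mapping.groupby("f")["c"].nunique() == 1).all()

    def test_indices_ordered_by_decreasing_size(self, tree):
        cut = cut_tree(tree, 4)
        sizes = cut.value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_out_of_range_k_rejected(self, tree):
        with pytest.raises(ValueError, match="out of range"):
            cut_tree(tree, 0)
        with pytest.raises(ValueError, match="out of range"):
            cut_tree(tree, 10)


class TestDetectOutliers:
    @staticmethod
    def _three_blobs_plus_outlier(seed=3):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [
                rng.standard_normal((10, 2)) * 0.2,
                rng.standard_normal((10, 2)) * 0.2 + [8, 0],
                rng.standard_normal((10, 2)) * 0.2 + [0, 8],
                [[100.0, 100.0]],
            ]
        )
        return centroid_linkage(pts, _ids(31))

    def test_far_singleton_flagged(self):
        tree = self._three_blobs_plus_outlier()
        out = detect_outliers(tree, n_primary=3, min_fraction=0.05)
        assert out.loc["s30", "outlier"]
        assert out.loc["s30", "cluster_index"] == -1
        assert out["outlier"].sum() == 1
        assert set(out.loc[~out["outlier"], "cluster_index"]) == {0, 1, 2}

    def test_clean_three_blob_data_has_no_outliers(self):
        rng = np.random.default_rng(4)
        pts = np.vstack(
            [rng.standard_normal((8, 2)) * 0.2 + [c, 0] for c in (0, 10, 20)]
        )
        tree = centroid_linkage(pts, _ids(24))
        out = detect_outliers(tree)
        assert not out["outlier"].any()

    def test_impossible_partition_raises(self):
        rng = np.random.default_rng(5)
        tree = centroid_linkage(rng.standard_normal((5, 2)), _ids(5))
        # three clusters of >= 0.4·5 = 2 members cannot coexist in 5 points
        with pytest.raises(ValueError, match="no cut"):
            detect_outliers(tree, n_primary=3, min_fraction=0.4)


class TestLabelAndMerge:
    @staticmethod
    def _assignment(cluster_sizes, outliers=0):
        idx = []
        cluster = []
        i = 0
        for c, size in enumerate(cluster_sizes):
            for _ in range(size):
                idx.append(f"s{i}")
                cluster.append(c)
                i += 1
        for _ in range(outliers):
            idx.append(f"s{i}")
            cluster.append(-1)
            i += 1
        return pd.DataFrame(
            {"cluster_index": cluster, "outlier": [c == -1 for c in cluster]},
            index=idx,
        )

    def test_labels_follow_mean_score_order(self):
        assignment = self._assignment([4, 4, 4])
        scores = pd.Series(
            [0.0] * 4 + [5.0] * 4 + [-5.0] * 4, index=assignment.index
        )
        outcomes = pd.Series(["pCR", "RD"] * 6, index=assignment.index)
        cls = label_and_merge(assignment, scores, outcomes)
        labels = cls.table["ordered_label"]
        assert set(labels[assignment["cluster_index"] == 1]) == {"high"}
        assert set(labels[assignment["cluster_index"] == 0]) == {"intermediate"}
        assert set(labels[assignment["cluster_index"] == 2]) == {"low"}
        assert cls.cluster_means["high"] == pytest.approx(5.0)

    def test_equal_rates_merge_into_til_low(self):
        assignment = self._assignment([4, 4, 4])
        scores = pd.Series([5.0] * 4 + [0.0] * 4 + [-5.0] * 4, index=assignment.index)
        outcomes = pd.Series(["pCR", "RD"] * 6, index=assignment.index)
        cls = label_and_merge(assignment, scores, outcomes)
        assert cls.merge_performed
        assert cls.merge_p == pytest.approx(1.0)
        binary = cls.table["binary_label"]
        assert set(binary[scores == 5.0]) == {"TIL-high"}
        assert set(binary[scores < 5.0]) == {"TIL-low"}

    def test_discordant_rates_withhold_merge(self):
        assignment = self._assignment([6, 10, 10])
        scores = pd.Series(
            [5.0] * 6 + [0.0] * 10 + [-5.0] * 10, index=assignment.index
        )
        outcomes = pd.Series(
            ["pCR"] * 6 + ["pCR"] * 10 + ["RD"] * 10, index=assignment.index
        )
        cls = label_and_merge(assignment, scores, outcomes)
        assert not cls.merge_performed
        assert cls.merge_p < 0.05
        binary = cls.table["binary_label"]
        assert set(binary[scores == 5.0]) == {"TIL-high"}
        assert set(binary[scores < 5.0]) == {"withheld"}

    def test_outliers_excluded_from_binary_call(self):
        assignment = self._assignment([4, 4, 4], outliers=2)
        scores = pd.Series(
            [5.0] * 4 + [0.0] * 4 + [-5.0] * 4 + [9.0, 9.0], index=assignment.index
        )
        outcomes = pd.Series(["pCR", "RD"] * 7, index=assignment.index)
        cls = label_and_merge(assignment, scores, outcomes)
        tail = cls.table.iloc[-2:]
        assert set(tail["ordered_label"]) == {"outlier"}
        assert set(tail["binary_label"]) == {"excluded"}

    def test_missing_outcome_for_whole_cluster_rejected(self):
        assignment = self._assignment([4, 4, 4])
        scores = pd.Series([5.0] * 4 + [0.0] * 4 + [-5.0] * 4, index=assignment.index)
        outcomes = pd.Series(
            ["pCR", "RD"] * 4 + [np.nan] * 4, index=assignment.index
        )
        with pytest.raises(ValueError, match="low cluster"):
            label_and_merge(assignment, scores, outcomes)

    def test_requires_three_primary_clusters(self):
        assignment = self._assignment([6, 6])
        scores = pd.Series(np.arange(12.0), index=assignment.index)
        outcomes = pd.Series(["pCR", "RD"] * 6, index=assignment.index)
        with pytest.raises(ValueError, match="3 primary"):
            label_and_merge(assignment, scores, outcomes)


class TestClassifyCases:
    def test_deterministic(self, normalized_default, default_cohort):
        outcomes = default_cohort.clinical.set_index("sample_id")["outcome"]
        a = classify_cases(normalized_default, list(CANONICAL_SIGNATURE), outcomes)
        b = classify_cases(normalized_default, list(CANONICAL_SIGNATURE), outcomes)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_high_label_tracks_latent_class(self):
        cohort = generate_cohort(SimulationConfig(seed=1, n_cases=300))
        norm = z_normalize_rows(cohort.expression)
        outcomes = cohort.clinical.set_index("sample_id")["outcome"]
        cls = classify_cases(norm, list(CANONICAL_SIGNATURE), outcomes)
        latent = pd.Series(cohort.latent_class)
        pred_high = cls.table["ordered_label"].loc[latent.index] == "high"
        true_high = latent == "high"
        assert (pred_high == true_high).mean() > 0.9

    def test_cluster_means_are_ordered(self, normalized_default, default_cohort):
        outcomes = default_cohort.clinical.set_index("sample_id")["outcome"]
        cls = classify_cases(normalized_default, list(CANONICAL_SIGNATURE), outcomes)
        m = cls.cluster_means
        assert m["high"] > m["intermediate"] > m["low"]

    def test_table_round_trip(self, tmp_path, normalized_default, default_cohort):
        outcomes = default_cohort.clinical.set_index("sample_id")["outcome"]
        cls = classify_cases(normalized_default, list(CANONICAL_SIGNATURE), outcomes)
        cls.to_tsv(tmp_path / "cls.tsv")
        back = pd.read_csv(tmp_path / "cls.tsv", sep="\t", index_col="sample_id")
        assert (back["ordered_label"] == cls.table["ordered_label"]).all()
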