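"""Feature assembly, scaling and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from conftest import average_linkage_oracle, label_purity
from tjmesh.classify import (
    MORPHO_COLUMNS,
    TEXTURE_COLUMNS,
    build_feature_matrix,
    cut_and_score,
    hcluster,
    pca_scores,
    scale_features,
)
from tjmesh.core import FeatureTable


def _roi_row(sample, roi, value, area=50.0, branches=20):
    row = {"sample_id": sample, "roi_id": roi}
    row.update({c: value for c in TEXTURE_COLUMNS})
    row.update({c: value for c in MORPHO_COLUMNS})
    row["pct_segmented_area"] = area
    row["n_branches"] = branches
    return row


def _table(rows):
    return FeatureTable(pd.DataFrame(rows))


class TestBuildFeatureMatrix:
    def test_single_roi_passthrough(self):
        out = build_feature_matrix(_table([_roi_row("s1", "r0", 3.0),
                                           _roi_row("s2", "r0", 5.0)]))
        assert len(out.data) == 2
        assert out.data.loc[0, "sum_average_d1"] == 3.0

    def test_two_rois_average(self):
        out = build_feature_matrix(
            _table([_roi_row("s1", "r0", 2.0), _roi_row("s1", "r1", 4.0),
                    _roi_row("s2", "r0", 1.0)])
        )
        s1 = out.data.set_index("sample_id").loc["s1"]
        assert s1["sum_variance_d3"] == pytest.approx(3.0)

    def test_sample_fully_dropped_by_qc_warns(self):
        rows = [_roi_row("good", "r0", 1.0),
                _roi_row("good", "r1", 1.0),
                _roi_row("bad", "r0", 1.0, area=5.0)]
        with pytest.warns(UserWarning, match="dropped entirely"):
            out = build_feature_matrix(_table(rows), mode="combined")
        assert list(out.data["sample_id"]) == ["good"]

    def test_texture_mode_keeps_only_texture_columns(self):
        out = build_feature_matrix(_table([_roi_row("a", "r0", 1.0),
                                           _roi_row("b", "r0", 2.0)]),
                                   mode="texture")
        assert set(out.feature_columns()) == set(TEXTURE_COLUMNS)


class TestScaleFeatures:
    def test_columns_centered_and_unit_variance(self, rng):
        df = pd.DataFrame(rng.random((10, 4)) * 100,
                          columns=["a", "b", "c", "d"])
        df.insert(0, "sample_id", [f"s{i}" for i in range(10)])
        out = scale_features(FeatureTable(df)).data
        for c in "abcd":
            assert abs(out[c].mean()) < 1e-12
            assert out[c].std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_zeroed_with_warning(self):
        df = pd.DataFrame({"sample_id": list("abc"), "x": [1.0, 2.0, 3.0],
                           "const": [7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning, match="constant columns"):
            out = scale_features(FeatureTable(df)).data
        np.testing.assert_array_equal(out["const"], 0.0)

    def test_ln_path_maps_zero_to_zero(self):
        df = pd.DataFrame({"sample_id": list("abc"), "x": [0.0, 1.0, 2.0]})
        out = scale_features(FeatureTable(df), ln_transform=True,
                             center=False).data
        # ln(0+1) = 0 before scaling; after unit-variance scaling it stays 0
        assert out.loc[0, "x"] == pytest.approx(0.0)

    def test_nan_rejected(self):
        df = pd.DataFrame({"sample_id": ["a", "b"], "x": [1.0, np.nan]})
        with pytest.raises(ValueError, match="NaN"):
            scale_features(FeatureTable(df))


class TestHcluster:
    def _table(self, X):
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        df.insert(0, "sample_id", [f"s{i}" for i in range(X.shape[0])])
        return FeatureTable(df)

    def test_identical_rows_merge_first_at_zero_height(self, rng):
        X = rng.random((5, 4))
        X[3] = X[1]
        dend = hcluster(self._table(X), metric="euclidean")
        first = dend.merges[0]
        assert {int(first[0]), int(first[1])} == {1, 3}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_distance_is_scale_invariant(self, rng):
        x = rng.random(6)
        X = np.vstack([x, 2 * x, rng.random(6)])
        dend = hcluster(self._table(X), metric="correlation")
        first = dend.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("metric", ["euclidean", "correlation"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_cubic_oracle(self, metric, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((8, 5))
        dend = hcluster(self._table(X), metric=metric)
        dists = squareform(pdist(X, metric=metric))
        heights, coph = average_linkage_oracle(dists)
        np.testing.assert_allclose(np.sort(dend.merges[:, 2]),
                                   np.sort(heights), atol=1e-10)
        np.testing.assert_allclose(dend.cophenetic_matrix(), coph, atol=1e-10)

    def test_merge_heights_non_decreasing(self, rng):
        X = rng.random((12, 6))
        dend = hcluster(self._table(X), metric="euclidean")
        assert np.all(np.diff(dend.merges[:, 2]) >= -1e-12)

    def test_permutation_equivariance(self, rng):
        X = rng.random((9, 4))
        perm = rng.permutation(9)
        d1 = hcluster(self._table(X), metric="euclidean")
        d2 = hcluster(self._table(X[perm]), metric="euclidean")
        c1 = d1.cophenetic_matrix()
        c2 = d2.cophenetic_matrix()
        np.testing.assert_allclose(c1[np.ix_(perm, perm)], c2, atol=1e-10)

    def test_constant_row_rejected_under_correlation(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="constant"):
            hcluster(self._table(X), metric="correlation")


class TestCutAndScore:
    def _cluster_table(self, rng, centers, n_per, spread=0.05):
        rows = []
        for ci, c in enumerate(centers):
            rows.append(c + rng.normal(0, spread, (n_per, len(c))))
        X = np.vstack(rows)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        df.insert(0, "sample_id", [f"s{i}" for i in range(len(X))])
        return FeatureTable(df), np.repeat(np.arange(len(centers)), n_per)

    def test_two_separated_blobs_select_k2(self, rng):
        table, truth = self._cluster_table(
            rng, [np.zeros(4), np.full(4, 5.0)], n_per=6
        )
        dend = hcluster(table, metric="euclidean")
        out = cut_and_score(dend, table, k_range=range(2, 6))
        assert out.k == 2
        assert label_purity(out.labels, truth) == 1.0

    def test_three_blobs_select_k3(self, rng):
        centers = [np.zeros(5), np.full(5, 4.0),
                   np.array([4.0, -4.0, 4.0, -4.0, 0.0])]
        table, truth = self._cluster_table(rng, centers, n_per=5, spread=0.2)
        dend = hcluster(table, metric="euclidean")
        out = cut_and_score(dend, table, k_range=range(2, 7))
        assert out.k == 3
        assert label_purity(out.labels, truth) == 1.0

    def test_k_range_of_one_rejected(self, rng):
        table, _ = self._cluster_table(rng, [np.zeros(3), np.ones(3)], 3)
        dend = hcluster(table, metric="euclidean")
        with pytest.raises(ValueError):
            cut_and_score(dend, table, k_range=[1])


class TestPca:
    def _table(self, X):
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        df.insert(0, "sample_id", [f"s{i}" for i in range(X.shape[0])])
        return FeatureTable(df)

    def test_rank_one_table_explains_everything_on_pc1(self, rng):
        u = rng.random(7)
        v = rng.random(4)
        X = np.outer(u, v)
        _, ev = pca_scores(self._table(X), n_components=2)
        assert ev[0] == pytest.approx(1.0)

    def test_rotation_preserves_explained_variance(self, rng):
        X = rng.random((10, 4))
        q, _ = np.linalg.qr(rng.random((4, 4)))
        _, ev1 = pca_scores(self._table(X), n_components=3)
        _, ev2 = pca_scores(self._table(X @ q), n_components=3)
        np.testing.assert_allclose(ev1, ev2, atol=1e-10)
        assert np.all(np.diff(ev1) <= 1e-12)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_scores(self._table(rng.random((4, 3))), n_components=4)
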