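import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evikit import outliers
from evikit._errors import ValidationError


def _records_from_points(points):
    points = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {"TR": 10 ** points[:, 0], "EVI": 10 ** points[:, 1]},
        index=[f"g{i}" for i in range(len(points))],
    )


class TestFitEllipse:
    def test_threshold_coefficient_at_n4(self):
        # 2(n+1)(n-1)/(n(n-2)) at n=4 is 3.75
        alpha = 0.05
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1.5]], dtype=float)
        model = outliers.fit_ellipse(pts, alpha=alpha)
        assert model.threshold == pytest.approx(3.75 * stats.f.ppf(1 - alpha, 2, 2))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError):
            outliers.fit_ellipse(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            outliers.fit_ellipse(np.zeros((3, 2)))

    def test_monte_carlo_coverage(self, rng):
        # empirical tail mass outside the prediction ellipse matches alpha
        pts = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 2]], size=8000)
        model = outliers.fit_ellipse(pts, alpha=0.05)
        outside = np.mean(model.mahalanobis_sq(pts) > model.threshold)
        assert outside == pytest.approx(0.05, abs=0.01)

    def test_mahalanobis_affine_invariance(self, rng):
        pts = rng.multivariate_normal([1, -2], [[1, 0.3], [0.3, 0.5]], size=500)
        A = np.array([[2.0, 0.7], [-0.3, 1.5]])
        b = np.array([5.0, -1.0])
        stat = outliers.fit_ellipse(pts).mahalanobis_sq(pts)
        stat_t = outliers.fit_ellipse(pts @ A.T + b).mahalanobis_sq(pts @ A.T + b)
        np.testing.assert_allclose(stat, stat_t, rtol=1e-8)


class TestClassifyGenes:
    def _fit(self, rng, n=2000):
        pts = rng.multivariate_normal([0, 0], [[0.1, 0.05], [0.05, 0.5]], size=n)
        return pts, outliers.fit_ellipse(pts, alpha=0.01)

    def test_center_is_inlier_with_zero_stat(self, rng):
        pts, model = self._fit(rng)
        rec = _records_from_points([model.center])
        out = outliers.classify_genes(model, rec)
        assert out["label"].iloc[0] == outliers.INLIER
        assert out["mahalanobis_stat"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_six_sd_below_is_low_evi(self, rng):
        pts, model = self._fit(rng)
        sd = model.axis_sd
        low = model.center + np.array([0.0, -6 * sd[1]])
        rec = _records_from_points([low])
        out = outliers.classify_genes(model, rec)
        assert out["label"].iloc[0] == outliers.LOW_EVI

    def test_single_high_tr_outlier_degenerate_path(self, rng):
        pts, model = self._fit(rng)
        high = model.center + np.array([6 * model.axis_sd[0], 0.0])
        out = outliers.classify_genes(model, _records_from_points([high]))
        assert out["label"].iloc[0] == outliers.HIGH_TR


def _ward_k2_objective(points, mask):
    """Sum over the two clusters of squared distances to the centroid."""
    total = 0.0
    for side in (mask, ~mask):
        if side.sum() == 0:
            return np.inf
        c = points[side].mean(axis=0)
        total += float(((points[side] - c) ** 2).sum())
    return total


class TestClusterOutliers:
    def _ellipse(self):
        return outliers.EllipseModel(
            center=np.zeros(2), covariance=np.eye(2), n=100, alpha=0.01,
            threshold=9.21,
        )

    def test_two_planted_blobs(self, rng):
        low = rng.normal([0, -3], 0.1, size=(10, 2))
        high = rng.normal([3, 0], 0.1, size=(10, 2))
        labels = outliers.cluster_outliers(np.vstack([low, high]), self._ellipse())
        assert all(l == outliers.LOW_EVI for l in labels[:10])
        assert all(l == outliers.HIGH_TR for l in labels[10:])

    def test_single_outlier_below_center(self):
        labels = outliers.cluster_outliers(np.array([[0.0, -3.0]]), self._ellipse())
        assert list(labels) == [outliers.LOW_EVI]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_ward_bipartition(self, seed):
        # cut-at-2 of Ward's linkage recovers the minimal k=2 Ward objective
        # on well-separated planted blobs
        rng = np.random.default_rng(seed)
        pts = np.vstack([
            rng.normal([0, -2.5], 0.4, size=(6, 2)),
            rng.normal([2.5, 0], 0.4, size=(6, 2)),
        ])
        labels = outliers.cluster_outliers(pts, self._ellipse())
        ours = labels == labels[0]
        best_mask, best_obj = None, np.inf
        for bits in itertools.product([True, False], repeat=len(pts) - 1):
            mask = np.array((True,) + bits)
            obj = _ward_k2_objective(pts, mask)
            if obj < best_obj:
                best_mask, best_obj = mask, obj
        assert np.array_equal(ours, best_mask) or np.array_equal(ours, ~best_mask)


class TestGreyQuadrant:
    def test_constructed_double_extreme_gene(self, rng):
        tr = rng.uniform(1, 2, size=200)
        evi = rng.uniform(1, 2, size=200)
        tr[17], evi[17] = 10.0, 0.01  # both max TR and min EVI
        rec = pd.DataFrame({"TR": tr, "EVI": evi},
                           index=[f"g{i}" for i in range(200)])
        assert outliers.grey_quadrant(rec, q=0.01) == ["g17"]

    def test_rank_correlated_metrics_give_empty_quadrant(self):
        x = np.linspace(1, 100, 500)
        rec = pd.DataFrame({"TR": x, "EVI": x}, index=[f"g{i}" for i in range(500)])
        assert outliers.grey_quadrant(rec, q=0.01) == []

    def test_independent_metrics_expected_size(self, rng):
        # under independence the expected count is n*q^2 = 1 at n=10000
        sizes = []
        for _ in range(10):
            rec = pd.DataFrame(
                {"TR": rng.normal(size=10_000), "EVI": rng.normal(size=10_000)},
                index=[f"g{i}" for i in range(10_000)],
            )
            sizes.append(len(outliers.grey_quadrant(rec, q=0.01)))
        assert 0 <= np.mean(sizes) < 4


class TestCompareGroupAnnotation:
    def test_clear_shift_mannwhitney(self):
        values = {f"a{i}": 1.0 + 0.01 * i for i in range(5)}
        values.update({f"b{i}": 2.0 + 0.01 * i for i in range(5)})
        res = outliers.compare_group_annotation(
            [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)], values,
            test="mannwhitney_onetailed", direction="less",
        )
        assert res["p_value"] < 0.05
        assert res["fold_of_means"] == pytest.approx(2.0, rel=0.01)

    def test_identical_samples_not_significant(self):
        values = {f"g{i}": float(i) for i in range(10)}
        res = outliers.compare_group_annotation(
            list(values), list(values), values,
            test="t_onetailed", direction="less",
        )
        assert res["p_value"] >= 0.5

    def test_undersized_group_rejected(self):
        values = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        with pytest.raises(ValidationError):
            outliers.compare_group_annotation(["a", "b"], ["c", "d"], values)
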