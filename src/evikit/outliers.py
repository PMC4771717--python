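"""Hotelling T^2 prediction-ellipse outlier detection on (log10 TR, log10 EVI).

For bivariate observations Z with sample mean Z_bar and unbiased covariance
S, the (1-alpha) prediction ellipse is the set of points with

    (Z - Z_bar)' S^-1 (Z - Z_bar) <= [2(n+1)(n-1) / (n(n-2))] F_{2,n-2}(1-alpha)

Genes outside the ellipse are outliers; they fall into two polarized
clusters (slow-elongation "low_EVI" and initiation-efficient "high_TR"),
separated here by Ward/Euclidean agglomerative clustering cut at k=2.
The "grey quadrant" (simultaneously top-q TR and bottom-q EVI) is tested
independently of the ellipse.  No multiple-testing correction is applied
anywhere; reported p-values are raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from ._errors import ValidationError
from .metrics import log_metrics, quantile_thresholds

logger = logging.getLogger(__name__)

INLIER, LOW_EVI, HIGH_TR = "inlier", "low_EVI", "high_TR"


@dataclass
class EllipseModel:
    """Fitted prediction ellipse on the (log10 TR, log10 EVI) plane."""

    center: np.ndarray      # sample mean, shape (2,)
    covariance: np.ndarray  # unbiased estimate S, shape (2, 2)
    n: int
    alpha: float
    threshold: float        # squared-Mahalanobis cutoff

    @property
    def axis_sd(self) -> np.ndarray:
        """Marginal standard deviations (log10 TR, log10 EVI)."""
        return np.sqrt(np.diag(self.covariance))

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        """(Z - Z_bar)' S^-1 (Z - Z_bar) for each row of ``points``."""
        diff = np.atleast_2d(points) - self.center
        solved = np.linalg.solve(self.covariance, diff.T)
        return np.einsum("ij,ji->i", diff, solved)

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "covariance": self.covariance.tolist(),
            "n": self.n,
            "alpha": self.alpha,
            "threshold": self.threshold,
        }


def prediction_threshold(n: int, alpha: float) -> float:
    """Squared-Mahalanobis cutoff of the bivariate (1-alpha) prediction ellipse."""
    if n <= 3:
        raise ValidationError(f"need n > 3 observations, got {n}")
    coef = 2.0 * (n + 1) * (n - 1) / (n * (n - 2))
    return coef * stats.f.ppf(1.0 - alpha, 2, n - 2)


def fit_ellipse(points: np.ndarray, alpha: float = 0.01) -> EllipseModel:
    """Fit the prediction ellipse to an n x 2 matrix of (log10 TR, log10 EVI)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValidationError("points must be an n x 2 matrix")
    n = points.shape[0]
    threshold = prediction_threshold(n, alpha)
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0 or eigvals.min() / eigvals.max() < 1e-12:
        raise np.linalg.LinAlgError(
            "singular covariance: points are (nearly) collinear, "
            "the prediction ellipse is undefined"
        )
    return EllipseModel(center=center, covariance=cov, n=n, alpha=alpha,
                        threshold=float(threshold))


def cluster_outliers(
    outlier_points: np.ndarray, ellipse: EllipseModel
) -> np.ndarray:
    """Split outliers into low_EVI and high_TR clusters.

    Agglomerative clustering (Euclidean distance, Ward linkage) cut at
    k=2; the cluster whose centroid has the lower log10 EVI is labeled
    ``low_EVI`` and the other ``high_TR``.  If one cluster minimizes EVI
    *and* maximizes TR, labels follow whichever centroid deviates more
    from the ellipse center in marginal-SD units along its axis.  With
    fewer than two outliers each point is labeled by its dominant axis
    deviation (degenerate path).
    """
    pts = np.atleast_2d(np.asarray(outlier_points, dtype=float))
    m = pts.shape[0]
    sd = ellipse.axis_sd
    if m < 2:
        logger.warning("cluster_outliers: only %d outlier(s); axis-deviation labels", m)
        labels = np.empty(m, dtype=object)
        for i, p in enumerate(pts):
            d_tr = (p[0] - ellipse.center[0]) / sd[0]
            d_evi = (p[1] - ellipse.center[1]) / sd[1]
            labels[i] = LOW_EVI if -d_evi >= d_tr else HIGH_TR
        return labels

    assignment = fcluster(linkage(pts, method="ward"), t=2, criterion="maxclust")
    centroids = np.array([pts[assignment == k].mean(axis=0) for k in (1, 2)])
    low_evi_cluster = int(np.argmin(centroids[:, 1])) + 1
    high_tr_cluster = int(np.argmax(centroids[:, 0])) + 1
    if low_evi_cluster == high_tr_cluster:
        c = centroids[low_evi_cluster - 1]
        dev_tr = (c[0] - ellipse.center[0]) / sd[0]
        dev_evi = -(c[1] - ellipse.center[1]) / sd[1]
        other = 3 - low_evi_cluster
        if dev_evi >= dev_tr:
            high_tr_cluster = other
        else:
            low_evi_cluster = other
    labels = np.where(assignment == low_evi_cluster, LOW_EVI, HIGH_TR).astype(object)
    return labels


def classify_genes(ellipse: EllipseModel, records: pd.DataFrame) -> pd.DataFrame:
    """Label every gene inlier / low_EVI / high_TR with its T^2 statistic.

    Returns a DataFrame indexed like ``records`` with columns
    ``log10TR``, ``log10EVI``, ``mahalanobis_stat`` and ``label``.
    """
    pts = log_metrics(records)
    stat = ellipse.mahalanobis_sq(pts)
    labels = np.full(len(records), INLIER, dtype=object)
    outside = stat > ellipse.threshold
    if outside.any():
        labels[outside] = cluster_outliers(pts[outside], ellipse)
    return pd.DataFrame(
        {
            "log10TR": pts[:, 0],
            "log10EVI": pts[:, 1],
            "mahalanobis_stat": stat,
            "label": labels,
        },
        index=records.index,
    )


def grey_quadrant(records: pd.DataFrame, q: float = 0.01) -> list[str]:
    """Genes simultaneously in the top-q of TR and the bottom-q of EVI.

    Independent of the ellipse fit; genes exactly at a threshold are
    included in the extreme set.
    """
    if len(records) < int(round(1 / q)):
        logger.warning("grey_quadrant: only %d genes for q=%g", len(records), q)
    tr_hi = quantile_thresholds(records["TR"], 1 - q)
    evi_lo = quantile_thresholds(records["EVI"], q)
    mask = (records["TR"] >= tr_hi) & (records["EVI"] <= evi_lo)
    return records.index[mask].tolist()


def compare_group_annotation(
    group: set[str] | list[str],
    background: set[str] | list[str],
    values: dict[str, float] | pd.Series,
    test: str = "t_onetailed",
    direction: str = "less",
) -> dict:
    """Compare a numeric gene annotation between a group and the background.

    ``test`` is one of ``t_onetailed``, ``mannwhitney_onetailed``,
    ``ks_twotailed``; ``direction`` states the alternative for the group
    relative to the background.  ``fold`` is the ratio of means oriented
    so that it is >1 when the data agree with ``direction``.
    """
    values = pd.Series(values)
    g = values.reindex(list(group)).dropna().to_numpy()
    b = values.reindex(list(background)).dropna().to_numpy()
    if len(g) < 3 or len(b) < 3:
        raise ValidationError(
            f"need >= 3 annotated genes per set, got {len(g)} and {len(b)}"
        )
    if direction not in ("less", "greater"):
        raise ValidationError(f"unknown direction {direction!r}")
    if test == "t_onetailed":
        stat, p = stats.ttest_ind(g, b, alternative=direction, equal_var=False)
    elif test == "mannwhitney_onetailed":
        stat, p = stats.mannwhitneyu(g, b, alternative=direction)
    elif test == "ks_twotailed":
        stat, p = stats.ks_2samp(g, b)
    else:
        raise ValidationError(f"unknown test {test!r}")
    if direction == "less":
        fold = float(np.mean(b) / np.mean(g))
    else:
        fold = float(np.mean(g) / np.mean(b))
    return {
        "test": test,
        "direction": direction,
        "statistic": float(stat),
        "p_value": float(p),
        "fold_of_means": fold,
        "n_group": int(len(g)),
        "n_background": int(len(b)),
    }
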