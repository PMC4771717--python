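"""Group-level codon-preference analytics.

Builds RSCU rows from pooled codon counts of gene groups (typically
low_EVI outliers, high_TR outliers, all genes, and a seeded random inlier
subset), runs PCA on the 61 sense-codon RSCU values, keeps the leading
components whose cumulative explained variance exceeds a threshold
(default 80%), clusters the groups by UPGMA on standardized Euclidean
distances, and correlates preference-score vectors across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from ._errors import ValidationError
from .codons import SENSE_CODONS, pooled_counts, rscu

logger = logging.getLogger(__name__)


def build_group_matrix(
    groups: Mapping[str, Sequence[str]], cds: Mapping[str, str]
) -> pd.DataFrame:
    """RSCU matrix: one row per gene group, one column per sense codon.

    Counts are pooled within each group before the RSCU computation;
    codons of families absent from a group are set to 0 (logged).
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 gene groups")
    rows = {}
    for label, genes in groups.items():
        genes = list(genes)
        if not genes:
            raise ValidationError(f"group {label!r} is empty")
        r = rscu(pooled_counts(genes, cds, source=label))
        missing = set(SENSE_CODONS) - set(r)
        if missing:
            logger.info("group %s: %d codons in absent families set to 0",
                        label, len(missing))
        rows[label] = [r.get(c, 0.0) for c in SENSE_CODONS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SENSE_CODONS))


def random_inlier_subset(
    inlier_genes: Sequence[str], size: int, seed: int
) -> list[str]:
    """Seeded random subset of inlier genes (reproducible control group)."""
    rng = np.random.default_rng(seed)
    inlier_genes = list(inlier_genes)
    size = min(size, len(inlier_genes))
    idx = rng.choice(len(inlier_genes), size=size, replace=False)
    return [inlier_genes[i] for i in sorted(idx)]


@dataclass
class PcaResult:
    """PCA of the group RSCU matrix with the retained-component count."""

    scores: pd.DataFrame           # groups x PCs
    explained: np.ndarray          # variance fractions, descending
    n_selected: int

    @property
    def selected_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_selected]


def pca_select(matrix: pd.DataFrame, threshold: float = 0.8) -> PcaResult:
    """Column-centered PCA; keep the fewest PCs explaining > ``threshold``.

    The explained-variance fractions sum to 1 over the nonzero PCs.
    """
    if len(matrix) < 2:
        raise ValidationError("PCA needs at least 2 rows")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X, X.mean(axis=0), atol=1e-15):
        raise ValidationError("zero-variance matrix: PCA undefined")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    scores = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    cum = np.cumsum(explained)
    n_selected = int(np.searchsorted(cum, threshold, side="right")) + 1
    n_selected = min(n_selected, len(explained))
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        explained=explained,
        n_selected=n_selected,
    )


@dataclass
class UpgmaResult:
    linkage_matrix: np.ndarray
    labels: list[str]
    cut2: dict[str, int]           # label -> cluster id at the 2-cluster cut
    newick: str

    def is_singleton_at_2cut(self, label: str) -> bool:
        """Is ``label`` alone in its cluster when the tree is cut at k=2?"""
        cluster = self.cut2[label]
        return sum(1 for v in self.cut2.values() if v == cluster) == 1


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:g},{right}:{dr:g})"


def upgma_cluster(scores: pd.DataFrame) -> UpgmaResult:
    """UPGMA (unweighted average linkage) on standardized Euclidean distances.

    Each retained dimension is scaled by its standard deviation across
    rows; zero-variance dimensions carry no information and are dropped.
    """
    if len(scores) < 2:
        raise ValidationError("UPGMA needs at least 2 rows")
    X = scores.to_numpy(dtype=float)
    var = X.var(axis=0, ddof=1)
    keep = var > 0
    if not keep.any():
        raise ValidationError("all dimensions have zero variance")
    d = pdist(X[:, keep], metric="seuclidean", V=var[keep])
    Z = linkage(d, method="average")
    labels = list(scores.index)
    flat = fcluster(Z, t=2, criterion="maxclust")
    newick = _newick(to_tree(Z), labels) + ";"
    return UpgmaResult(
        linkage_matrix=Z,
        labels=labels,
        cut2=dict(zip(labels, (int(v) for v in flat))),
        newick=newick,
    )


def ps_correlation_matrix(
    ps_by_condition: Mapping[str, Mapping[str, float]],
) -> dict[str, pd.DataFrame]:
    """Pairwise Spearman/Pearson correlation of preference-score vectors.

    Correlations use the codons defined in both conditions of each pair
    (at least 3 required).  Returns symmetric DataFrames ``spearman_r``,
    ``spearman_p``, ``pearson_r``, ``pearson_p`` with unit diagonal.
    """
    conditions = list(ps_by_condition)
    if len(conditions) < 2:
        raise ValidationError("need at least 2 conditions")
    mats = {
        k: pd.DataFrame(np.eye(len(conditions)), index=conditions, columns=conditions)
        for k in ("spearman_r", "pearson_r")
    }
    mats["spearman_p"] = pd.DataFrame(np.zeros((len(conditions),) * 2),
                                      index=conditions, columns=conditions)
    mats["pearson_p"] = mats["spearman_p"].copy()
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            shared = sorted(set(ps_by_condition[a]) & set(ps_by_condition[b]))
            if len(shared) < 3:
                raise ValidationError(
                    f"conditions {a!r} and {b!r} share only {len(shared)} codons"
                )
            x = np.array([ps_by_condition[a][c] for c in shared])
            y = np.array([ps_by_condition[b][c] for c in shared])
            rs, ps = stats.spearmanr(x, y)
            rp, pp = stats.pearsonr(x, y)
            for key, val in (("spearman_r", rs), ("spearman_p", ps),
                             ("pearson_r", rp), ("pearson_p", pp)):
                mats[key].loc[a, b] = mats[key].loc[b, a] = float(val)
    return mats
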