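"""Per-gene translation metrics derived from the three abundance layers.

With M, C and F the rpkM abundances of total mRNA, ribosome-nascent-chain
(RNC) mRNA and ribosome footprints:

* translation ratio        TR  = C / M   (relative initiation efficiency)
* elongation velocity index EVI = C^2 / (M * F)  (relative elongation speed)
* ribosome density          D  = F / C = TR / EVI

All three are unitless ratios of rpkM values, so they can be compared
across genes; EVI is only a *relative* measure of elongation speed.
Downstream geometry and statistics operate on log10(TR) and log10(EVI),
which span several log units on real translatomes.
"""

from __future__ import annotations

import logging
from math import log2

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .io import ExpressionTable

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["M", "C", "F", "TR", "EVI", "D"]


def derive_metrics(
    m_table: ExpressionTable,
    c_table: ExpressionTable,
    f_table: ExpressionTable,
    min_rpkm: float = 0.1,
) -> pd.DataFrame:
    """Derive TR, EVI and D for genes quantified in all three layers.

    Only genes with M, C, F >= ``min_rpkm`` and strictly positive in every
    layer are retained (the rest cannot be quantified reliably); the
    filtered count is logged.  Returns a DataFrame indexed by gene_id with
    columns M, C, F, TR, EVI, D.
    """
    for t in (m_table, c_table, f_table):
        if t.unit != "rpkM":
            raise ValidationError(f"layer {t.layer} is in {t.unit}, expected rpkM")
    df = pd.concat(
        [m_table.to_series(), c_table.to_series(), f_table.to_series()],
        axis=1, join="inner",
    )
    df.columns = ["M", "C", "F"]
    n_total = len(df)
    keep = (df >= max(min_rpkm, 0.0)).all(axis=1) & (df > 0).all(axis=1)
    df = df[keep].copy()
    logger.info("derive_metrics: kept %d of %d genes (min_rpkm=%g)",
                len(df), n_total, min_rpkm)
    df["TR"] = df["C"] / df["M"]
    df["EVI"] = df["C"] ** 2 / (df["M"] * df["F"])
    df["D"] = df["F"] / df["C"]
    return df


def quantile_thresholds(values, q: float) -> float:
    """Empirical quantile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("quantile of an empty vector")
    if not 0 < q < 1:
        raise ValidationError("q must be in (0, 1)")
    if values.size < 10:
        logger.warning("quantile on only %d values", values.size)
    return float(np.quantile(values, q))


def _safe_corr(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson/Spearman with NaN for degenerate (zero-variance) input."""
    if np.std(x) == 0 or np.std(y) == 0 or len(x) < 3:
        return {"pearson_r": float("nan"), "pearson_p": float("nan"),
                "spearman_r": float("nan"), "spearman_p": float("nan")}
    rp, pp = stats.pearsonr(x, y)
    rs, ps = stats.spearmanr(x, y)
    return {"pearson_r": float(rp), "pearson_p": float(pp),
            "spearman_r": float(rs), "spearman_p": float(ps)}


def differential_metrics(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    fold: float = 10.0,
    labels: tuple[str, str] = ("a", "b"),
) -> tuple[pd.DataFrame, dict]:
    """Between-condition log2 fold changes of TR and EVI.

    ``log2fc_X = log2(X_a / X_b)`` over genes quantified in both
    conditions.  The summary reports Pearson and Spearman correlations of
    the two fold changes and the gene lists beyond the +/-``fold``
    threshold on EVI (the relative-EVI gene lists).
    """
    common = records_a.index.intersection(records_b.index)
    if len(common) == 0:
        raise ValidationError("conditions share no quantified genes")
    a = records_a.loc[common]
    b = records_b.loc[common]
    diff = pd.DataFrame(
        {
            "log2fc_TR": np.log2(a["TR"] / b["TR"]),
            "log2fc_EVI": np.log2(a["EVI"] / b["EVI"]),
        },
        index=common,
    )
    cut = log2(fold)
    up = diff.index[diff["log2fc_EVI"] > cut].tolist()
    down = diff.index[diff["log2fc_EVI"] < -cut].tolist()
    summary = {
        "condition_a": labels[0],
        "condition_b": labels[1],
        "n_genes": int(len(common)),
        "fold_threshold": fold,
        "evi_up_genes": up,
        "evi_down_genes": down,
        **_safe_corr(diff["log2fc_TR"].to_numpy(), diff["log2fc_EVI"].to_numpy()),
    }
    return diff, summary


def log_metrics(records: pd.DataFrame) -> np.ndarray:
    """(log10 TR, log10 EVI) matrix in the record order, for the ellipse fit."""
    return np.column_stack(
        [np.log10(records["TR"].to_numpy()), np.log10(records["EVI"].to_numpy())]
    )
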