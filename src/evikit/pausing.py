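"""Translational pause-site calling from footprint coverage.

A gene's pause candidate is the position of its highest footprint peak
within the CDS; the call is positive when the peak depth exceeds 10x the
mean CDS depth (peak included in the mean).  Peaks at least 240 nt
downstream of the start codon are associated with co-translational
folding, so each call also records which side of that boundary it falls
on.  Raw depth is used throughout (no P-site offsetting or read-length
stratification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .io import CoverageProfile, GeneModel

logger = logging.getLogger(__name__)

PAUSE_FOLD_THRESHOLD = 10.0
FOLDING_BOUNDARY_NT = 240


@dataclass
class PauseCall:
    """Highest-footprint-peak call for one gene."""

    gene_id: str
    peak_offset: int     # nt, 0-based from the first nt of the start codon
    peak_fold: float     # peak depth / mean CDS depth
    is_pause: bool       # peak_fold > fold threshold
    after_240: bool      # peak_offset >= 240


def call_pause(
    profile: CoverageProfile, fold_threshold: float = PAUSE_FOLD_THRESHOLD
) -> PauseCall:
    """Call the highest CDS peak; leftmost position wins ties."""
    cds = np.asarray(profile.cds_depth, dtype=float)
    mean = cds.mean()
    if mean == 0:
        raise ValidationError(f"{profile.gene_id}: all-zero CDS coverage")
    offset = int(np.argmax(cds))  # argmax is leftmost-tie-breaking
    fold = float(cds[offset] / mean)
    return PauseCall(
        gene_id=profile.gene_id,
        peak_offset=offset,
        peak_fold=fold,
        is_pause=fold > fold_threshold,
        after_240=offset >= FOLDING_BOUNDARY_NT,
    )


def calls_to_frame(calls: Iterable[PauseCall]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "peak_offset": c.peak_offset,
                "peak_fold": c.peak_fold,
                "is_pause": c.is_pause,
                "after_240": c.after_240,
            }
            for c in calls
        ]
    )
    return df.set_index("gene_id") if len(df) else df


def peak_histogram(
    calls: Sequence[PauseCall], bin_width: int = 40, cap: int = 400
) -> pd.DataFrame:
    """Percentage distribution of highest-peak offsets.

    Offsets >= ``cap`` are counted in the final bin; percentages sum
    to 100.
    """
    if not calls:
        raise ValidationError("no pause calls to histogram")
    offsets = np.array([min(c.peak_offset, cap) for c in calls])
    edges = np.arange(0, cap + bin_width, bin_width, dtype=float)
    if edges[-1] < cap + 1:
        edges = np.append(edges, cap + 1)
    else:
        edges[-1] = cap + 1
    counts, _ = np.histogram(offsets, bins=edges)
    percent = 100.0 * counts / counts.sum()
    return pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(int),
            "bin_end": np.minimum(edges[1:], cap + 1).astype(int),
            "percent": percent,
        }
    )


def compare_peak_distributions(
    group_a: Sequence[int],
    group_b: Sequence[int],
    threshold: int = FOLDING_BOUNDARY_NT,
) -> dict:
    """Two-sided two-sample KS test on raw (uncapped) peak offsets.

    Also reports each group's fraction of peaks before ``threshold`` nt.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError(f"need >= 3 offsets per group, got {len(a)}, {len(b)}")
    stat, p = stats.ks_2samp(a, b)
    return {
        "ks_statistic": float(stat),
        "p_value": float(p),
        "fraction_before_a": float(np.mean(a < threshold)),
        "fraction_before_b": float(np.mean(b < threshold)),
        "threshold_nt": threshold,
    }


@dataclass
class MetageneProfile:
    """Average per-gene-normalized footprint depth around the start codon."""

    offsets: np.ndarray
    mean_normalized_depth: np.ndarray
    n_genes: int

    @property
    def post_start_max(self) -> float:
        """Highest normalized depth at or after the start codon (artifact check)."""
        return float(self.mean_normalized_depth[self.offsets >= 0].max())


def metagene_profile(
    profiles: Iterable[CoverageProfile],
    min_rfp_reads: int = 200,
    window: tuple[int, int] = (-20, 200),
) -> MetageneProfile:
    """Start-codon metagene of well-expressed genes.

    Genes with fewer than ``min_rfp_reads`` total footprint reads are
    dropped.  Each gene's window (offsets relative to the first CDS nt)
    is normalized by its own mean over the window, then averaged across
    genes position-wise; positions outside a transcript are skipped for
    that gene.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    n_genes = 0
    for prof in profiles:
        if prof.total_reads < min_rfp_reads:
            continue
        start = prof.model.cds_start
        pos = start + offsets
        valid = (pos >= 0) & (pos < prof.model.mrna_length)
        depth = prof.depth[pos[valid]]
        mean = depth.mean() if len(depth) else 0.0
        if mean == 0:
            logger.debug("metagene: %s has empty window, skipped", prof.gene_id)
            continue
        sums[valid] += depth / mean
        counts[valid] += 1
        n_genes += 1
    if n_genes == 0:
        raise ValidationError(
            f"no gene passes the {min_rfp_reads}-read metagene filter"
        )
    with np.errstate(invalid="ignore"):
        mean_profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetageneProfile(offsets=offsets, mean_normalized_depth=mean_profile,
                           n_genes=n_genes)


def evi_length_correlation(
    records: pd.DataFrame, models: Mapping[str, GeneModel]
) -> dict:
    """Spearman/Pearson correlation of log10 EVI with CDS length (nt)."""
    genes = [g for g in records.index if g in models]
    if len(genes) < 10:
        raise ValidationError(f"need >= 10 genes with models, got {len(genes)}")
    log_evi = np.log10(records.loc[genes, "EVI"].to_numpy())
    lengths = np.array([models[g].cds_length for g in genes], dtype=float)
    if np.std(log_evi) == 0 or np.std(lengths) == 0:
        nan = float("nan")
        return {"spearman_r": nan, "spearman_p": nan,
                "pearson_r": nan, "pearson_p": nan, "n": len(genes)}
    rs, ps = stats.spearmanr(log_evi, lengths)
    rp, pp = stats.pearsonr(log_evi, lengths)
    return {"spearman_r": float(rs), "spearman_p": float(ps),
            "pearson_r": float(rp), "pearson_p": float(pp), "n": len(genes)}
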