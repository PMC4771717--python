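"""Seeded synthetic translatome generator with known planted structure.

The generator emits exactly what the readers in :mod:`evikit.io` consume:
coding sequences (FASTA), gene models, M/C/F abundance tables in rpkM for
one or two conditions, and per-transcript footprint coverage — plus a
:class:`SyntheticTruth` record of everything that was planted (slow
codons, low-EVI and high-TR gene sets, true log TR/EVI, pause positions)
so downstream modules can be scored against ground truth.

What it emulates: gene abundances spanning several log units, a positive
rank correlation between log TR and log EVI (default target Spearman
0.62), a small fraction of genes displaced several SDs down in log EVI
(slow-elongation outliers, enriched in designated slow codons) or up in
log TR (initiation-efficient outliers), and footprint coverage with
pause peaks well above the 10x calling threshold — placed at least
240 nt after the start codon for the slow genes and within the first
240 nt for the high-TR genes.  It does not model read-level noise,
positional sequencing bias or codon-resolution dwell times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import pi, sin
from typing import Mapping

import numpy as np

from ._errors import ValidationError
from .codons import SENSE_CODONS
from .io import CoverageProfile, ExpressionTable, GeneModel

DEFAULT_SLOW_CODONS = ("ATA", "GGG", "CTA", "CCG", "ACG")


@dataclass
class SyntheticTruth:
    """Planted parameters of one synthetic dataset."""

    seed: int
    slow_codons: tuple[str, ...]
    low_evi_genes: list[str] = field(default_factory=list)
    high_tr_genes: list[str] = field(default_factory=list)
    true_log_tr: dict[str, float] = field(default_factory=dict)
    true_log_evi: dict[str, float] = field(default_factory=dict)
    pause_positions: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.low_evi_genes) & set(self.high_tr_genes):
            raise ValidationError("planted gene groups must be disjoint")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "slow_codons": list(self.slow_codons),
            "low_evi_genes": self.low_evi_genes,
            "high_tr_genes": self.high_tr_genes,
            "true_log_tr": self.true_log_tr,
            "true_log_evi": self.true_log_evi,
            "pause_positions": self.pause_positions,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_genome(
    n_genes: int = 5000,
    length_log_mean: float = 5.6,
    length_log_sd: float = 0.35,
    background_usage: Mapping[str, float] | None = None,
    slow_codons: tuple[str, ...] = DEFAULT_SLOW_CODONS,
    slow_enrichment: float = 4.0,
    slow_gene_fraction: float = 0.01,
    high_tr_gene_fraction: float = 0.01,
    utr5: int = 60,
    utr3: int = 120,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, GeneModel], SyntheticTruth]:
    """Generate coding sequences and gene models with planted slow genes.

    Gene lengths (in codons, including start and stop) are log-normal
    with natural-log parameters ``length_log_mean``/``length_log_sd``
    (defaults give a median of ~270 codons).  Each CDS is ATG + sampled
    sense codons + TAA.  Planted slow (future low-EVI) genes sample the
    designated slow codons with their background frequency multiplied by
    ``slow_enrichment`` and the vector renormalized.
    """
    rng = np.random.default_rng(seed)
    codons = np.array(SENSE_CODONS)
    if background_usage is None:
        freq = np.full(len(codons), 1.0 / len(codons))
    else:
        freq = np.array([background_usage.get(c, 0.0) for c in codons], dtype=float)
        if np.any(freq < 0) or freq.sum() <= 0:
            raise ValidationError("background_usage must be non-negative, nonzero")
        freq = freq / freq.sum()
    slow_idx = np.array([i for i, c in enumerate(codons) if c in slow_codons])
    if len(slow_idx) != len(slow_codons):
        raise ValidationError("slow_codons must be sense codons")
    slow_freq = freq.copy()
    slow_freq[slow_idx] *= slow_enrichment
    slow_freq = slow_freq / slow_freq.sum()

    width = len(str(n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    n_slow = int(round(slow_gene_fraction * n_genes))
    n_high = int(round(high_tr_gene_fraction * n_genes))
    planted = rng.choice(n_genes, size=n_slow + n_high, replace=False)
    low_evi = sorted(gene_ids[i] for i in planted[:n_slow])
    high_tr = sorted(gene_ids[i] for i in planted[n_slow : n_slow + n_high])
    low_set = set(low_evi)

    n_codons = np.maximum(
        np.rint(rng.lognormal(length_log_mean, length_log_sd, size=n_genes)), 10
    ).astype(int)

    cds: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    for gid, length in zip(gene_ids, n_codons):
        p = slow_freq if gid in low_set else freq
        body = rng.choice(codons, size=length - 2, p=p)
        seq = "ATG" + "".join(body) + "TAA"
        cds[gid] = seq
        cds_len = 3 * length
        models[gid] = GeneModel(
            gene_id=gid,
            transcript_ids=[gid],
            mrna_length=utr5 + cds_len + utr3,
            cds_start=utr5,
            cds_end=utr5 + cds_len,
        )
    truth = SyntheticTruth(
        seed=seed,
        slow_codons=tuple(slow_codons),
        low_evi_genes=low_evi,
        high_tr_genes=high_tr,
        params={
            "n_genes": n_genes,
            "length_log_mean": length_log_mean,
            "length_log_sd": length_log_sd,
            "slow_enrichment": slow_enrichment,
            "slow_gene_fraction": slow_gene_fraction,
            "high_tr_gene_fraction": high_tr_gene_fraction,
            "utr5": utr5,
            "utr3": utr3,
        },
    )
    return cds, models, truth


def generate_translatome(
    truth: SyntheticTruth,
    mu_log_m: float = 1.0,
    sigma_log_m: float = 0.8,
    rho: float = 0.62,
    sd_log_tr: float = 0.35,
    sd_log_evi: float = 1.0,
    outlier_displacement_sd: float = 4.0,
    noise_sd: float = 0.1,
    couple_evi_to_codons: bool = False,
    cds: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[ExpressionTable, ExpressionTable, ExpressionTable, SyntheticTruth]:
    """Simulate the three rpkM layers from a planted (log TR, log EVI) field.

    (log10 TR, log10 EVI) is bivariate normal with target *Spearman*
    correlation ``rho`` (converted to the Pearson parameter via
    2*sin(pi*rho/6)).  Planted low-EVI genes are displaced
    ``-outlier_displacement_sd`` marginal SDs in log EVI and high-TR
    genes displaced the same amount upward in log TR.  M is log-normal
    (log10 mean/sd ``mu_log_m``/``sigma_log_m``), C = TR*M and
    F = C*TR/EVI, after which independent multiplicative log-normal
    measurement noise of log10-SD ``noise_sd`` is applied per layer.

    With ``couple_evi_to_codons`` the displacement of each planted slow
    gene is scaled by its actual slow-codon usage relative to the planted
    expectation, making codon-preference recovery a genuine end-to-end
    test (requires ``cds``).
    """
    if not -1 < rho < 1:
        raise ValidationError("rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.true_log_tr) if truth.true_log_tr else None
    if genes is None:
        n = truth.params.get("n_genes")
        if n is None:
            raise ValidationError("truth lacks gene inventory")
        width = len(str(n))
        genes = [f"g{i + 1:0{width}d}" for i in range(n)]
    n = len(genes)

    r_pearson = 2.0 * sin(pi * rho / 6.0)
    cov = np.array(
        [
            [sd_log_tr**2, r_pearson * sd_log_tr * sd_log_evi],
            [r_pearson * sd_log_tr * sd_log_evi, sd_log_evi**2],
        ]
    )
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    log_tr = z[:, 0]
    log_evi = z[:, 1]

    index = {g: i for i, g in enumerate(genes)}
    scale = {g: 1.0 for g in truth.low_evi_genes}
    if couple_evi_to_codons:
        if cds is None:
            raise ValidationError("couple_evi_to_codons requires cds sequences")
        slow = set(truth.slow_codons)
        usage = {}
        for g in truth.low_evi_genes:
            seq = cds[g]
            total = len(seq) // 3
            n_slow = sum(
                1 for i in range(0, len(seq), 3) if seq[i : i + 3] in slow
            )
            usage[g] = n_slow / total
        mean_usage = np.mean(list(usage.values())) if usage else 1.0
        scale = {g: usage[g] / mean_usage for g in usage}
    for g in truth.low_evi_genes:
        if g in index:
            log_evi[index[g]] -= outlier_displacement_sd * sd_log_evi * scale[g]
    for g in truth.high_tr_genes:
        if g in index:
            log_tr[index[g]] += outlier_displacement_sd * sd_log_tr

    log_m = rng.normal(mu_log_m, sigma_log_m, size=n)
    m = 10.0**log_m
    tr = 10.0**log_tr
    evi = 10.0**log_evi
    c = tr * m
    f = c * tr / evi  # inverts EVI = C^2/(M*F)
    layers = []
    for values, layer in ((m, "mRNA"), (c, "RNC"), (f, "RFP")):
        noisy = values * 10.0 ** rng.normal(0.0, noise_sd, size=n)
        layers.append(
            ExpressionTable(layer=layer, unit="rpkM",
                            values=dict(zip(genes, noisy.astype(float))))
        )
    truth.true_log_tr = dict(zip(genes, log_tr.astype(float)))
    truth.true_log_evi = dict(zip(genes, log_evi.astype(float)))
    truth.params.update(
        {
            "mu_log_m": mu_log_m,
            "sigma_log_m": sigma_log_m,
            "rho": rho,
            "sd_log_tr": sd_log_tr,
            "sd_log_evi": sd_log_evi,
            "outlier_displacement_sd": outlier_displacement_sd,
            "noise_sd": noise_sd,
            "couple_evi_to_codons": couple_evi_to_codons,
        }
    )
    return layers[0], layers[1], layers[2], truth


def generate_coverage(
    truth: SyntheticTruth,
    models: Mapping[str, GeneModel],
    mean_depth: float = 10.0,
    pause_fold: float = 20.0,
    pause_after_240: bool = True,
    start_ramp: float | None = None,
    seed: int = 0,
) -> dict[str, CoverageProfile]:
    """Poisson footprint coverage with planted pause peaks.

    Every position draws Poisson(``mean_depth``).  Planted low-EVI genes
    get one peak of ``pause_fold`` x mean at a uniform CDS offset >= 240
    (anywhere if ``pause_after_240`` is off); high-TR genes get their
    maximum within the first 240 nt.  ``start_ramp`` optionally
    multiplies the mean over the first 15 nt of every CDS (drug-artifact
    emulation).  Planted positions are recorded in the truth.
    """
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    low = set(truth.low_evi_genes)
    high = set(truth.high_tr_genes)
    profiles: dict[str, CoverageProfile] = {}
    for gid in sorted(models):
        model = models[gid]
        lam = np.full(model.mrna_length, mean_depth)
        if start_ramp:
            lam[model.cds_start : model.cds_start + 15] *= start_ramp
        peak_offset = None
        cds_len = model.cds_length
        if gid in low:
            lo = 240 if (pause_after_240 and cds_len > 243) else 0
            peak_offset = int(rng.integers(lo, cds_len - 3))
        elif gid in high:
            peak_offset = int(rng.integers(0, min(240, cds_len - 3)))
        depth = rng.poisson(lam).astype(float)
        if peak_offset is not None:
            pos = model.cds_start + peak_offset
            depth[pos] = max(rng.poisson(pause_fold * mean_depth), 1)
            truth.pause_positions[gid] = peak_offset
        profiles[gid] = CoverageProfile(gene_id=gid, depth=depth, model=model)
    truth.params.update(
        {"mean_depth": mean_depth, "pause_fold": pause_fold,
         "pause_after_240": pause_after_240, "start_ramp": start_ramp}
    )
    return profiles
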