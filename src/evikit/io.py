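"""Readers, writers and normalization for the pipeline's external formats.

Three abundance layers are handled throughout: total mRNA (``mRNA``),
ribosome-nascent-chain-bound mRNA (``RNC``) and ribosome footprints
(``RFP``).  Expression tables are plain TSV with a header naming at least
``gene_id`` and ``value``; coverage is 4-column bedGraph in transcript
coordinates (0-based, half-open); coding sequences come from FASTA.
Counts are normalized to rpkM (reads per kilobase of transcript per
million mapped reads) with the 1e9 scale constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

LAYERS = ("mRNA", "RNC", "RFP")
UNITS = ("count", "rpkM")

#: scale constant of the rpkM unit: reads * 1e9 / (nt * mapped reads)
RPKM_SCALE = 1e9


@dataclass
class GeneModel:
    """Transcript-coordinate gene model (strandless).

    ``cds_start``/``cds_end`` delimit the coding region as a 0-based
    half-open interval on the (merged) transcript; the CDS length must be
    a whole number of codons.
    """

    gene_id: str
    transcript_ids: list[str]
    mrna_length: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.mrna_length <= 0:
            raise ValidationError(f"{self.gene_id}: mrna_length must be positive")
        if not (0 <= self.cds_start < self.cds_end <= self.mrna_length):
            raise ValidationError(
                f"{self.gene_id}: need 0 <= cds_start < cds_end <= mrna_length, "
                f"got {self.cds_start}, {self.cds_end}, {self.mrna_length}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


@dataclass
class ExpressionTable:
    """Per-gene abundances of one sequencing layer in one unit."""

    layer: str
    unit: str
    values: dict[str, float]
    total_mapped_reads: int | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        for gene, v in self.values.items():
            if v < 0:
                raise ValidationError(f"negative value {v} for gene {gene!r}")
        if self.unit == "count":
            if self.total_mapped_reads is None:
                raise ValidationError("count tables require total_mapped_reads")
            if self.total_mapped_reads <= 0:
                raise ValidationError("total_mapped_reads must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        s.index.name = "gene_id"
        s.name = self.layer
        return s


@dataclass
class CoverageProfile:
    """Per-nucleotide footprint depth along one (merged) transcript."""

    gene_id: str
    depth: np.ndarray
    model: GeneModel = field(repr=False)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) != self.model.mrna_length:
            raise ValidationError(
                f"{self.gene_id}: depth length {len(self.depth)} != "
                f"mrna_length {self.model.mrna_length}"
            )
        if np.any(self.depth < 0):
            raise ValidationError(f"{self.gene_id}: negative depth")

    @property
    def cds_depth(self) -> np.ndarray:
        return self.depth[self.model.cds_start : self.model.cds_end]

    @property
    def total_reads(self) -> float:
        return float(self.depth.sum())


def read_expression_table(
    path: str | Path,
    layer: str,
    unit: str,
    total_mapped_reads: int | None = None,
) -> ExpressionTable:
    """Read a delimited per-gene abundance table.

    The file must have header columns ``gene_id`` and ``value`` (extra
    columns are ignored).  For count tables, ``total_mapped_reads``
    defaults to the column sum.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = {"gene_id", "value"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"{path}: duplicate gene_id(s) {dups[:5]}")
    values = dict(zip(df["gene_id"].astype(str), df["value"].astype(float)))
    if unit == "count" and total_mapped_reads is None:
        total_mapped_reads = int(round(df["value"].sum()))
    return ExpressionTable(layer=layer, unit=unit, values=values,
                           total_mapped_reads=total_mapped_reads)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    s = table.to_series().sort_index()
    pd.DataFrame({"gene_id": s.index, "value": s.values}).to_csv(
        path, sep="\t", index=False
    )


def compute_rpkm(table: ExpressionTable, lengths: Mapping[str, int]) -> ExpressionTable:
    """Convert a count table to rpkM: 1e9 * count / (length_nt * mapped reads)."""
    if table.unit != "count":
        raise ValidationError("compute_rpkm expects a count table")
    total = table.total_mapped_reads
    out: dict[str, float] = {}
    for gene, count in table.values.items():
        if gene not in lengths:
            raise KeyError(f"no length for gene {gene!r}")
        length = lengths[gene]
        if length <= 0:
            raise ValidationError(f"non-positive length for gene {gene!r}")
        out[gene] = RPKM_SCALE * count / (length * total)
    return ExpressionTable(layer=table.layer, unit="rpkM", values=out)


def normalize_layers(
    m_table: ExpressionTable,
    c_table: ExpressionTable,
    f_table: ExpressionTable,
    models: Mapping[str, GeneModel],
    rfp_cds_only: bool = False,
) -> tuple[ExpressionTable, ExpressionTable, ExpressionTable]:
    """Convert the three count layers to rpkM using gene-model lengths.

    M and C always normalize over the full (merged) transcript length.
    F does too by default — symmetric with C and M — but with
    ``rfp_cds_only`` it normalizes over the CDS length instead, the
    variant that excludes upstream-ORF footprints from the elongation
    signal.
    """
    tx_len = {g: mod.mrna_length for g, mod in models.items()}
    cds_len = {g: mod.cds_length for g, mod in models.items()}
    return (
        compute_rpkm(m_table, tx_len),
        compute_rpkm(c_table, tx_len),
        compute_rpkm(f_table, cds_len if rfp_cds_only else tx_len),
    )


def merge_splice_variants(
    table: ExpressionTable,
    mapping: Mapping[str, str] | Iterable[tuple[str, str]],
    models: Mapping[str, GeneModel],
) -> tuple[ExpressionTable, dict[str, GeneModel]]:
    """Merge transcript-level counts into gene level.

    Counts are summed over a gene's transcripts; the merged gene length is
    the maximum transcript length (CDS coordinates of that longest
    transcript are kept).  rpkM must be recomputed after merging, never
    averaged, so only count tables are accepted.
    """
    if table.unit != "count":
        raise ValidationError("merge before normalization: pass a count table")
    if not isinstance(mapping, Mapping):
        pairs = list(mapping)
        mapping = {}
        for tx, gene in pairs:
            if tx in mapping and mapping[tx] != gene:
                raise KeyError(f"transcript {tx!r} mapped to multiple genes")
            mapping[tx] = gene

    gene_counts: dict[str, float] = {}
    gene_txs: dict[str, list[str]] = {}
    for tx, count in table.values.items():
        if tx not in mapping:
            raise KeyError(f"transcript {tx!r} has no gene in the mapping")
        gene = mapping[tx]
        gene_counts[gene] = gene_counts.get(gene, 0.0) + count
        gene_txs.setdefault(gene, []).append(tx)

    gene_models: dict[str, GeneModel] = {}
    for gene, txs in gene_txs.items():
        longest = max(txs, key=lambda t: models[t].mrna_length)
        m = models[longest]
        gene_models[gene] = GeneModel(
            gene_id=gene,
            transcript_ids=sorted(txs),
            mrna_length=m.mrna_length,
            cds_start=m.cds_start,
            cds_end=m.cds_end,
        )
    merged = ExpressionTable(
        layer=table.layer,
        unit="count",
        values=gene_counts,
        total_mapped_reads=table.total_mapped_reads,
    )
    return merged, gene_models


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read a gene-model TSV: gene_id, transcript_id, length, cds_start, cds_end."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = {"gene_id", "transcript_id", "length", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    models: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        tx = str(row.transcript_id)
        if tx in models:
            raise ValidationError(f"{path}: duplicate transcript_id {tx!r}")
        models[tx] = GeneModel(
            gene_id=str(row.gene_id),
            transcript_ids=[tx],
            mrna_length=int(row.length),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
        )
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "transcript_id": tx,
            "length": m.mrna_length,
            "cds_start": m.cds_start,
            "cds_end": m.cds_end,
        }
        for m in models.values()
        for tx in (m.transcript_ids or [m.gene_id])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path, models: Mapping[str, GeneModel]) -> dict[str, CoverageProfile]:
    """Read bedGraph-style coverage rows into dense per-gene depth vectors.

    Rows are ``(transcript_or_gene_id, start, end, depth)`` with 0-based
    half-open intervals.  Positions not covered by any row are 0; every
    gene in ``models`` gets a profile even if it has no rows.  Overlapping
    intervals and intervals running past the transcript end are rejected.
    """
    depths = {g: np.zeros(m.mrna_length, dtype=float) for g, m in models.items()}
    covered = {g: np.zeros(m.mrna_length, dtype=bool) for g, m in models.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            gene, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if gene not in models:
                raise ValidationError(f"{path}:{lineno}: unknown id {gene!r}")
            if not (0 <= start < end <= models[gene].mrna_length):
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start},{end}) outside "
                    f"transcript of length {models[gene].mrna_length}"
                )
            if depth < 0:
                raise ValidationError(f"{path}:{lineno}: negative depth")
            if covered[gene][start:end].any():
                raise ValidationError(f"{path}:{lineno}: overlapping interval for {gene!r}")
            depths[gene][start:end] = depth
            covered[gene][start:end] = True
    return {
        g: CoverageProfile(gene_id=g, depth=d, model=models[g])
        for g, d in depths.items()
    }


def write_coverage(profiles: Mapping[str, CoverageProfile], path: str | Path) -> None:
    """Write dense depth vectors as run-length-merged bedGraph rows."""
    with open(path, "w") as fh:
        for gene in sorted(profiles):
            depth = profiles[gene].depth
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(depth)]))
            for s, e in zip(starts, ends):
                d = depth[s]
                if d != 0:
                    fh.write(f"{gene}\t{s}\t{e}\t{d:g}\n")


_VALID_NT = set("ACGTN")


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read coding sequences; uppercase, U->T, first header token is the id."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = record.id
        if gene in seqs:
            raise ValidationError(f"{path}: duplicate FASTA header {gene!r}")
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_NT
        if bad:
            raise ValidationError(f"{path}: invalid nucleotide(s) {sorted(bad)} in {gene!r}")
        seqs[gene] = seq
    return seqs


def write_cds_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gene in sorted(seqs):
            fh.write(f">{gene}\n")
            seq = seqs[gene]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def intersect_layers(*tables: ExpressionTable) -> list[ExpressionTable]:
    """Restrict tables to genes quantified in every layer; logs the drop count."""
    common = set(tables[0].values)
    for t in tables[1:]:
        common &= set(t.values)
    out = []
    for t in tables:
        dropped = len(t.values) - len(common)
        if dropped:
            logger.info("layer %s: dropped %d genes absent from other layers", t.layer, dropped)
        out.append(
            ExpressionTable(
                layer=t.layer,
                unit=t.unit,
                values={g: v for g, v in t.values.items() if g in common},
                total_mapped_reads=t.total_mapped_reads,
            )
        )
    return out
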