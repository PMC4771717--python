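"""Codon-level statistics: counts, RSCU, PS, CAI, CBI, Nc, tAI, PCAA.

All indices use the standard nuclear genetic code and the 61 sense codons;
stop codons are excluded everywhere.  Definitions:

* RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij) — observed count of codon j of
  amino acid i over its expected count under equal synonymous usage.
* PS = log2(RSCU_group / RSCU_background) — a positive preference score
  marks a codon favored by the gene group.
* CAI = exp((1/L) * sum log(f_i / max_j f_j)) — geometric-mean relative
  adaptiveness against a reference codon-frequency set (Sharp & Li).
* CBI = (N_pfr - N_ran) / (N_tot - N_ran) — excess usage of preferred
  codons over the equal-usage expectation (Bennetzen & Hall).
* Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 — effective number of codons from
  the average synonymous homozygosity per degeneracy class (Wright).
* tAI — tRNA adaptation index from anticodon gene copy numbers with
  wobble-pairing penalties (dos Reis et al.).
* PCAA — fraction of positively charged amino acids (K, R, H).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from math import exp, fsum, log, log2
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats

from ._errors import ValidationError

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: degeneracy (synonymous family size) per sense codon
FAMILY_SIZE: dict[str, int] = {
    c: len(AA_TO_CODONS[CODON_TO_AA[c]]) for c in SENSE_CODONS
}

#: positively charged amino acids
PCAA_RESIDUES = frozenset("KRH")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CodonCounts:
    """Tally over the 61 sense codons for a gene or pooled gene group."""

    counts: Counter = field(default_factory=Counter)
    source: str = ""
    skipped: int = 0  # stop codons and codons containing N/ambiguity

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValidationError(f"non-sense-codon keys {sorted(bad)}")

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(
            counts=self.counts + other.counts,
            source=f"{self.source}+{other.source}",
            skipped=self.skipped + other.skipped,
        )

    def total(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in AA_TO_CODONS[aa])


def codon_counts(cds: str, source: str = "", require_start: bool = False) -> CodonCounts:
    """Tally sense codons of a CDS; stops and N-containing codons are skipped."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValidationError(f"{source or 'CDS'}: length {len(cds)} not divisible by 3")
    if require_start and cds[:3] != "ATG":
        raise ValidationError(f"{source or 'CDS'}: does not begin with ATG")
    counts: Counter = Counter()
    skipped = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in CODON_TO_AA:
            counts[codon] += 1
        else:
            skipped += 1
    if skipped:
        logger.debug("%s: skipped %d stop/ambiguous codons", source, skipped)
    return CodonCounts(counts=counts, source=source, skipped=skipped)


def pooled_counts(genes: Iterable[str], cds: Mapping[str, str], source: str = "") -> CodonCounts:
    """Pool codon counts over a gene group (counts are sufficient statistics)."""
    out = CodonCounts(source=source)
    for g in genes:
        c = codon_counts(cds[g], source=g)
        out.counts.update(c.counts)
        out.skipped += c.skipped
    return out


def rscu(counts: CodonCounts, pseudocount: float = 0.0) -> dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    Families with zero total are left absent unless ``pseudocount`` > 0,
    in which case the pseudocount is added to every codon of the family.
    """
    out: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        x = [float(counts.counts.get(c, 0)) for c in codons]
        total = sum(x)
        if total == 0:
            if pseudocount <= 0:
                continue
            x = [pseudocount] * len(codons)
            total = pseudocount * len(codons)
        expected = total / len(codons)
        for c, xi in zip(codons, x):
            out[c] = xi / expected
    return out


def preference_score(
    group_counts: CodonCounts,
    background_counts: CodonCounts,
    pseudocount: float = 0.5,
) -> dict[str, float]:
    """PS = log2(RSCU_group / RSCU_background) per codon.

    The pseudocount (default 0.5) is added to every raw count before the
    RSCU computation so the log ratio stays defined at zero counts; with
    pseudocount 0, codons with zero RSCU in either vector are absent.
    """

    def _padded_rscu(counts: CodonCounts) -> dict[str, float]:
        if pseudocount <= 0:
            return rscu(counts)
        padded = CodonCounts(
            counts=Counter({c: counts.counts.get(c, 0) + pseudocount
                            for c in SENSE_CODONS}),
            source=counts.source,
        )
        return rscu(padded)

    g = _padded_rscu(group_counts)
    b = _padded_rscu(background_counts)
    return {
        c: log2(g[c] / b[c])
        for c in SENSE_CODONS
        if c in g and c in b and g[c] > 0 and b[c] > 0
    }


def codon_chisq(
    group_counts: CodonCounts, background_counts: CodonCounts, codon: str
) -> tuple[float, float]:
    """Two-tailed chi-square test of one codon's usage within its family.

    2x2 contingency: rows = {group, background}, columns = {this codon,
    other synonymous codons of the same amino acid}; no continuity
    correction.
    """
    if codon not in CODON_TO_AA:
        raise ValidationError(f"{codon!r} is not a sense codon")
    aa = CODON_TO_AA[codon]
    g_c = group_counts.counts.get(codon, 0)
    b_c = background_counts.counts.get(codon, 0)
    g_rest = group_counts.family_total(aa) - g_c
    b_rest = background_counts.family_total(aa) - b_c
    if g_c + g_rest == 0 or b_c + b_rest == 0:
        raise ValidationError(f"family of {codon} ({aa}) absent in one of the sets")
    table = np.array([[g_c, g_rest], [b_c, b_rest]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        # one column empty in both sets: no usage difference detectable
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def relative_adaptiveness(
    reference: CodonCounts, floor: float = 0.5
) -> dict[str, float]:
    """CAI weights w = f / max(f) within each synonymous family.

    Zero reference counts are floored at ``floor`` (a fractional count)
    before normalization so log weights stay finite.
    """
    w: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        x = [max(float(reference.counts.get(c, 0)), floor) for c in codons]
        m = max(x)
        for c, xi in zip(codons, x):
            w[c] = xi / m
    return w


def cai(counts: CodonCounts, weights: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Single-codon amino acids (ATG, TGG) do not discriminate and are
    excluded from L.
    """
    log_sum = 0.0
    L = 0
    for codon, n in counts.counts.items():
        if FAMILY_SIZE[codon] == 1:
            continue
        if codon not in weights:
            raise ValidationError(f"no reference weight for codon {codon}")
        log_sum += n * log(weights[codon])
        L += n
    if L == 0:
        raise ValidationError("no multi-codon-family codons: CAI undefined")
    return exp(log_sum / L)


def preferred_codons_from_reference(reference: CodonCounts) -> dict[str, str]:
    """Default CBI preferred set: the argmax-RSCU codon per multi-codon amino acid."""
    r = rscu(reference, pseudocount=0.5)
    preferred: dict[str, str] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) == 1:
            continue
        preferred[aa] = max(codons, key=lambda c: (r.get(c, 0.0), c))
    return preferred


def cbi(counts: CodonCounts, preferred: Mapping[str, Iterable[str] | str]) -> float:
    """Codon bias index over the amino acids with a declared preferred set.

    N_pfr = occurrences of preferred codons; N_ran = expected preferred
    occurrences under equal synonymous usage; N_tot = all occurrences of
    the included amino acids.
    """
    n_pfr = 0.0
    n_ran = 0.0
    n_tot = 0.0
    for aa, pref in preferred.items():
        pref_set = {pref} if isinstance(pref, str) else set(pref)
        codons = AA_TO_CODONS[aa]
        if not pref_set <= set(codons):
            raise ValidationError(f"preferred codons {pref_set} not synonymous for {aa}")
        count_aa = counts.family_total(aa)
        n_tot += count_aa
        n_ran += count_aa * len(pref_set) / len(codons)
        n_pfr += sum(counts.counts.get(c, 0) for c in pref_set)
    if n_tot == n_ran:
        raise ValidationError("N_tot == N_ran: CBI undefined (no discriminating family)")
    return (n_pfr - n_ran) / (n_tot - n_ran)


#: degeneracy classes of the standard code: 9 two-fold, 1 three-fold,
#: 5 four-fold, 3 six-fold amino acids (Met and Trp are single-codon)
_DEGENERACY_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


def enc(counts: CodonCounts) -> float:
    """Effective number of codons, Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.

    F_hat for one amino acid with n observed codons and within-family
    fractions p_i is (n * sum p_i^2 - 1) / (n - 1); F_k averages F_hat
    over the amino acids of degeneracy k.  Wright's fallbacks: an
    undefined amino acid is covered by its class average; an entirely
    undefined 3-fold class borrows the mean of F2 and F4.  The result is
    clamped to [20, 61].
    """
    f_hat_by_class: dict[int, list[float]] = {k: [] for k in _DEGENERACY_CLASSES}
    for aa, codons in AA_TO_CODONS.items():
        k = len(codons)
        if k == 1:
            continue
        n = counts.family_total(aa)
        if n < 2:
            continue  # homozygosity estimator needs >= 2 observations
        p = np.array([counts.counts.get(c, 0) for c in codons], dtype=float) / n
        f_hat = (n * float(np.sum(p**2)) - 1.0) / (n - 1.0)
        if f_hat > 0:
            f_hat_by_class[k].append(f_hat)

    f_mean: dict[int, float] = {
        k: fsum(v) / len(v) for k, v in f_hat_by_class.items() if v
    }
    if 3 not in f_mean and 2 in f_mean and 4 in f_mean:
        f_mean[3] = (f_mean[2] + f_mean[4]) / 2.0
    if not f_mean:
        raise ValidationError("no synonymous family computable: Nc undefined")

    nc = 2.0
    for k, n_aa in _DEGENERACY_CLASSES.items():
        if k in f_mean:
            nc += n_aa / f_mean[k]
        else:
            # class entirely unobserved: F=1 (single codon per amino acid)
            logger.debug("Nc: degeneracy class %d unobserved, assuming F=1", k)
            nc += n_aa
    return float(min(max(nc, 20.0), 61.0))


@dataclass
class TaiWeights:
    """Normalized tRNA-adaptation weights per sense codon."""

    w: dict[str, float]
    tgcn: dict[str, int]
    s: dict[str, float]


#: dos Reis et al. wobble-pairing selective constraints, by codon third base:
#: each codon is read by its Watson-Crick anticodon (s=0) plus one wobble
#: anticodon with the listed penalty.
DEFAULT_WOBBLE_S = {"G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68}

# codon third base -> (wobble anticodon 5' base, penalty key)
_WOBBLE_RULE = {"T": ("G", "G:U"), "C": ("A", "I:C"), "A": ("A", "I:A"), "G": ("T", "U:G")}


def tai_weights(
    tgcn: Mapping[str, int], s: Mapping[str, float] | None = None
) -> TaiWeights:
    """tAI codon weights from anticodon gene copy numbers (tGCN).

    W_codon = sum over recognizing anticodons of (1 - s_pair) * tGCN;
    weights are normalized by the maximum, and zero weights are replaced
    by the geometric mean of the nonzero ones.  Anticodons are given as
    DNA 5'->3' (e.g. codon AAA is read by anticodon TTT).
    """
    s = dict(DEFAULT_WOBBLE_S, **(s or {}))
    tgcn = {k.upper().replace("U", "T"): int(v) for k, v in tgcn.items()}
    if all(v == 0 for v in tgcn.values()) or not tgcn:
        raise ValidationError("all tGCN are zero: tAI weights undefined")
    raw: dict[str, float] = {}
    for codon in SENSE_CODONS:
        watson_crick = _revcomp(codon)
        total = float(tgcn.get(watson_crick, 0))
        wobble_base, key = _WOBBLE_RULE[codon[2]]
        wobble_anticodon = wobble_base + watson_crick[1:]
        if wobble_anticodon != watson_crick:
            total += (1.0 - s[key]) * tgcn.get(wobble_anticodon, 0)
        raw[codon] = total
    w_max = max(raw.values())
    if w_max == 0:
        raise ValidationError("no codon has a recognizing tRNA")
    w = {c: v / w_max for c, v in raw.items()}
    nonzero = [v for v in w.values() if v > 0]
    geo = exp(fsum(log(v) for v in nonzero) / len(nonzero))
    w = {c: (v if v > 0 else geo) for c, v in w.items()}
    return TaiWeights(w=w, tgcn=tgcn, s=s)


def tai(counts: CodonCounts, weights: TaiWeights) -> float:
    """Gene tAI: geometric mean of codon weights over the gene's codons."""
    total = counts.total()
    if total == 0:
        raise ValidationError("empty codon counts: tAI undefined")
    log_sum = fsum(n * log(weights.w[c]) for c, n in counts.counts.items())
    return exp(log_sum / total)


def pcaa_fraction(sequence: str, on_internal_stop: str = "error") -> float:
    """Fraction of positively charged residues (K, R, H) in a protein.

    Accepts a CDS (translated with the standard code; a trailing stop is
    dropped) or an amino-acid sequence.  ``on_internal_stop`` is
    ``"error"`` or ``"truncate"``.
    """
    seq = sequence.upper().replace("U", "T")
    if set(seq) <= set("ACGTN") and len(seq) % 3 == 0 and seq:
        peptide = str(Seq(seq).translate())
        if peptide.endswith("*"):
            peptide = peptide[:-1]
        if "*" in peptide:
            if on_internal_stop == "truncate":
                peptide = peptide.split("*", 1)[0]
            else:
                raise ValidationError("internal stop codon in CDS")
    else:
        peptide = seq
        if "*" in peptide:
            peptide = peptide.replace("*", "")
    if not peptide:
        raise ValidationError("empty peptide: PCAA fraction undefined")
    return sum(1 for r in peptide if r in PCAA_RESIDUES) / len(peptide)
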