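from collections import Counter
from math import sqrt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evikit import codons
from evikit._errors import ValidationError
from evikit.codons import AA_TO_CODONS, CodonCounts, SENSE_CODONS


def _counts(mapping):
    return CodonCounts(counts=Counter(mapping))


class TestCodonCounts:
    def test_stop_skipped(self):
        c = codons.codon_counts("ATGAAATAG")
        assert dict(c.counts) == {"ATG": 1, "AAA": 1}
        assert c.skipped == 1

    def test_ambiguous_codon_skipped(self):
        c = codons.codon_counts("ATGNNNAAA")
        assert dict(c.counts) == {"ATG": 1, "AAA": 1}
        assert c.skipped == 1

    def test_frame_violation_rejected(self):
        with pytest.raises(ValidationError):
            codons.codon_counts("ATGA")

    def test_counts_additive_over_concatenation(self, rng):
        a = "".join(rng.choice(SENSE_CODONS, size=50))
        b = "".join(rng.choice(SENSE_CODONS, size=70))
        joint = codons.codon_counts(a + b).counts
        assert joint == codons.codon_counts(a).counts + codons.codon_counts(b).counts


class TestRscu:
    def test_two_fold_family(self):
        r = codons.rscu(_counts({"AAA": 3, "AAG": 1}))
        assert r["AAA"] == pytest.approx(1.5)
        assert r["AAG"] == pytest.approx(0.5)

    def test_equal_usage_is_one(self):
        r = codons.rscu(_counts({"GGT": 2, "GGC": 2, "GGA": 2, "GGG": 2}))
        assert all(r[c] == pytest.approx(1.0) for c in AA_TO_CODONS["G"])

    def test_concentrated_four_fold_family(self):
        r = codons.rscu(_counts({"GGT": 4}))
        assert r["GGT"] == pytest.approx(4.0)
        assert r["GGC"] == 0.0

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_family_sum_equals_family_size(self, a, b, c, d):
        # sum of RSCU over an observed family equals its degeneracy
        counts = _counts({"GGT": a, "GGC": b, "GGA": c, "GGG": d})
        r = codons.rscu(counts)
        if a + b + c + d > 0:
            total = sum(r[x] for x in AA_TO_CODONS["G"])
            assert total == pytest.approx(4.0)


class TestPreferenceScore:
    def test_worked_log_ratios_without_pseudocount(self):
        group = _counts({"GGT": 10, "GGC": 10, "GGA": 0, "GGG": 0})   # RSCU(GGT)=2
        background = _counts({"GGT": 5, "GGC": 5, "GGA": 5, "GGG": 5})  # RSCU=1
        ps = codons.preference_score(group, background, pseudocount=0)
        assert ps["GGT"] == pytest.approx(1.0)

    def test_self_comparison_is_zero(self, rng):
        counts = _counts({c: int(n) for c, n in
                          zip(SENSE_CODONS, rng.integers(0, 30, len(SENSE_CODONS)))})
        ps = codons.preference_score(counts, counts)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in ps.values())

    def test_antisymmetric_under_swap(self, rng):
        a = _counts({c: int(n) for c, n in
                     zip(SENSE_CODONS, rng.integers(1, 30, len(SENSE_CODONS)))})
        b = _counts({c: int(n) for c, n in
                     zip(SENSE_CODONS, rng.integers(1, 30, len(SENSE_CODONS)))})
        ab = codons.preference_score(a, b)
        ba = codons.preference_score(b, a)
        for c in ab:
            assert ab[c] == pytest.approx(-ba[c])

    def test_negative_score_for_disfavored_codon(self):
        group = _counts({"AAA": 1, "AAG": 3})      # RSCU(AAA)=0.5
        background = _counts({"AAA": 3, "AAG": 0})  # RSCU(AAA)=2 with pc=0
        ps = codons.preference_score(group, background, pseudocount=0)
        assert ps["AAA"] == pytest.approx(-2.0)


class TestCodonChisq:
    def test_identical_proportions(self):
        g = _counts({"GGT": 10, "GGC": 10})
        b = _counts({"GGT": 1000, "GGC": 1000})
        chi2, p = codons.codon_chisq(g, b, "GGT")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_extreme_skew_significant(self):
        g = _counts({"GGT": 50, "GGC": 0})
        b = _counts({"GGT": 500, "GGC": 500})
        chi2, p = codons.codon_chisq(g, b, "GGT")
        # closed-form 2x2 chi-square: N(ad-bc)^2 / row/col products
        n = 50 + 500 + 500
        expected = n * (50 * 500 - 0 * 500) ** 2 / (50 * 1000 * 550 * 500)
        assert chi2 == pytest.approx(expected)
        assert p < 1e-6

    def test_family_absent_rejected(self):
        g = _counts({"GGT": 5})
        b = _counts({"AAA": 5, "AAG": 5})
        with pytest.raises(ValidationError):
            codons.codon_chisq(g, b, "AAA")


class TestCai:
    def test_all_maximal_codons_score_one(self):
        ref = _counts({"AAA": 90, "AAG": 10, "GGT": 80, "GGC": 10, "GGA": 5, "GGG": 5})
        w = codons.relative_adaptiveness(ref)
        gene = _counts({"AAA": 7, "GGT": 3})
        assert codons.cai(gene, w) == pytest.approx(1.0)

    def test_two_codon_worked_case(self):
        # ratios {0.5, 1.0} -> exp(ln(0.5)/2) ~ 0.7071
        ref = _counts({"AAA": 100, "AAG": 50, "GGT": 100, "GGC": 1, "GGA": 1, "GGG": 1})
        w = codons.relative_adaptiveness(ref)
        gene = _counts({"AAG": 1, "GGT": 1})
        assert codons.cai(gene, w) == pytest.approx(sqrt(0.5), rel=1e-6)

    def test_single_codon_amino_acids_rejected(self):
        ref = _counts({"AAA": 1})
        w = codons.relative_adaptiveness(ref)
        with pytest.raises(ValidationError):
            codons.cai(_counts({"ATG": 3, "TGG": 2}), w)


class TestCbi:
    def test_all_preferred(self):
        assert codons.cbi(_counts({"AAA": 10}), {"K": "AAA"}) == pytest.approx(1.0)

    def test_random_usage(self):
        assert codons.cbi(_counts({"AAA": 5, "AAG": 5}), {"K": "AAA"}) == pytest.approx(0.0)

    def test_worked_two_fold_case(self):
        # 10 Lys codons, 8 preferred, expectation 5 -> (8-5)/(10-5) = 0.6
        assert codons.cbi(_counts({"AAA": 8, "AAG": 2}), {"K": "AAA"}) == pytest.approx(0.6)

    def test_no_discriminating_family_rejected(self):
        with pytest.raises(ValidationError):
            codons.cbi(_counts({}), {"K": "AAA"})


class TestEnc:
    def test_single_codon_usage_hits_lower_bound(self):
        counts = {}
        for aa, family in AA_TO_CODONS.items():
            counts[family[0]] = 10
        assert codons.enc(_counts(counts)) == pytest.approx(20.0)

    def test_uniform_usage_near_61(self):
        per_codon = 6000 // len(SENSE_CODONS)
        counts = {c: per_codon for c in SENSE_CODONS}
        assert codons.enc(_counts(counts)) == pytest.approx(61.0, abs=0.5)

    def test_three_fold_fallback_used(self):
        # no Ile observations: F3 borrows the mean of F2 and F4
        counts = {"AAA": 5, "AAG": 5, "GGT": 5, "GGC": 5, "GGA": 5, "GGG": 5}
        value = codons.enc(_counts(counts))
        assert 20.0 <= value <= 61.0

    def test_concentration_decreases_enc(self, rng):
        uniform = {c: 50 for c in SENSE_CODONS}
        skewed = dict(uniform)
        skewed["GGT"], skewed["GGC"] = 95, 5  # move Gly counts to the majority codon
        assert codons.enc(_counts(skewed)) < codons.enc(_counts(uniform))

    def test_no_family_computable_rejected(self):
        with pytest.raises(ValidationError):
            codons.enc(_counts({"ATG": 5}))


class TestTai:
    def test_isolated_anticodons_all_weights_one(self):
        # anticodons whose wobble partners are absent: every supplied codon
        # keeps the same raw weight, normalizing to 1
        tgcn = {"TTT": 4}  # reads AAA (Watson-Crick)
        weights = codons.tai_weights(tgcn, s={"U:G": 1.0})
        assert weights.w["AAA"] == pytest.approx(1.0)

    def test_geometric_mean_worked_case(self):
        # w(AAA)=1 and w(AAG)=0.25 via the U:G wobble penalty 0.75
        weights = codons.tai_weights({"TTT": 4}, s={"U:G": 0.75})
        assert weights.w["AAG"] == pytest.approx(0.25)
        gene = _counts({"AAA": 5, "AAG": 5})
        assert codons.tai(gene, weights) == pytest.approx(0.5)

    def test_zero_tgcn_rejected(self):
        with pytest.raises(ValidationError):
            codons.tai_weights({"TTT": 0})

    def test_zero_weight_codons_use_geometric_mean(self):
        weights = codons.tai_weights({"TTT": 4, "GAT": 2}, s={"U:G": 0.5})
        nonzero = [v for v in weights.w.values()]
        assert all(v > 0 for v in nonzero)


class TestPcaa:
    @pytest.mark.parametrize(
        "seq,expected",
        [("KRHA", 0.75), ("AAAA", 0.0), ("AAACGTCATGCG", 0.75)],
    )
    def test_fractions(self, seq, expected):
        assert codons.pcaa_fraction(seq) == pytest.approx(expected)

    def test_internal_stop_rejected_by_default(self):
        with pytest.raises(ValidationError):
            codons.pcaa_fraction("AAATAAAAA")

    def test_internal_stop_truncation(self):
        assert codons.pcaa_fraction("AAATAAGCG", on_internal_stop="truncate") == 1.0


class TestPoolingSufficiency:
    def test_indices_from_pooled_counts_match_concatenated_gene(self, rng):
        genes = ["".join(rng.choice(SENSE_CODONS, size=100)) for _ in range(4)]
        pooled = codons.pooled_counts(range(4), dict(enumerate(genes)))
        concat = codons.codon_counts("".join(genes))
        assert pooled.counts == concat.counts
        assert codons.enc(pooled) == pytest.approx(codons.enc(concat))
        ref = _counts({c: 10 for c in SENSE_CODONS})
        w = codons.relative_adaptiveness(ref)
        assert codons.cai(pooled, w) == pytest.approx(codons.cai(concat, w))
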