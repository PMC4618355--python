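"""Sequence- and biophysics-property calculators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xenoflux import seqprops as sp
from xenoflux.synthetic_data import gen_codon_reference, gen_thermogram


class TestCodonFrequencies:
    def test_single_family_codon(self):
        table = sp.codon_frequencies("ATGGCGGCG")
        assert table.family_freq["GCG"] == pytest.approx(1.0)
        assert table.argmax_codon["A"] == "GCG"

    def test_within_family_fraction(self, ala_skewed_table):
        # GCG x2, GCA x1 -> 2/3 within the Ala family
        assert ala_skewed_table.family_freq["GCG"] == pytest.approx(2 / 3)
        assert ala_skewed_table.family_freq["GCA"] == pytest.approx(1 / 3)

    def test_family_frequencies_sum_to_one(self):
        orf, _ = gen_codon_reference(seed=5)
        table = sp.codon_frequencies(orf)
        by_aa = {}
        for codon, f in table.family_freq.items():
            aa = sp._CODON_TO_AA[codon]
            by_aa[aa] = by_aa.get(aa, 0.0) + f
        for aa, total in by_aa.items():
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_argmax_is_family_maximal(self):
        orf, _ = gen_codon_reference(seed=5)
        table = sp.codon_frequencies(orf)
        for aa, codon in table.argmax_codon.items():
            fam = [c for c in sp._FAMILY[aa] if c in table.family_freq]
            assert table.family_freq[codon] == max(table.family_freq[c] for c in fam)

    @pytest.mark.parametrize(
        "bad,err", [("ATGC", sp.FrameError), ("ATGXXG", sp.InvalidAlphabetError)]
    )
    def test_rejects_bad_input(self, bad, err):
        with pytest.raises(err):
            sp.codon_frequencies(bad)


class TestBackTranslate:
    @pytest.mark.parametrize("aa,dna", [("M", "ATG"), ("MW", "ATGTGG")])
    def test_single_codon_families(self, aa, dna, ala_skewed_table):
        assert sp.back_translate(aa, ala_skewed_table) == dna

    def test_uses_argmax_codon(self, ala_skewed_table):
        assert sp.back_translate("A", ala_skewed_table) == "GCG"

    def test_missing_residue_named_in_error(self, ala_skewed_table):
        with pytest.raises(sp.MissingCodonError, match="K"):
            sp.back_translate("K", ala_skewed_table)

    def test_protein_level_round_trip(self):
        orf, _ = gen_codon_reference(seed=2)
        protein = sp.translate(orf)
        table = sp.codon_frequencies(orf)
        dna = sp.back_translate(protein, table)
        assert len(dna) == 3 * len(protein)
        assert sp.translate(dna) == protein


class TestGcContent:
    @pytest.mark.parametrize("dna,expect", [("GGCC", 100.0), ("ATAT", 0.0), ("ATGC", 50.0)])
    def test_examples(self, dna, expect):
        assert sp.gc_content(dna) == pytest.approx(expect)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.gc_content("")


class TestNetCharge:
    def test_no_ionizable_side_chains(self):
        assert sp.net_charge("GGG") == 0.0

    def test_basic_residues_hh_oracle(self):
        # each K: +1/(1+10^(7-10.54))
        pka = dict(sp.DEFAULT_PKA, K=10.54)
        per_k = 1.0 / (1.0 + 10 ** (7.0 - 10.54))
        assert sp.net_charge("KKK", ph=7.0, pka=pka) == pytest.approx(3 * per_k)
        assert sp.net_charge("KKK", ph=7.0, pka=pka) == pytest.approx(3.0, abs=0.01)

    def test_acidic_residues_hh_oracle(self):
        pka = dict(sp.DEFAULT_PKA, D=3.71)
        per_d = -1.0 / (1.0 + 10 ** (3.71 - 7.0))
        assert sp.net_charge("DDDD", ph=7.0, pka=pka) == pytest.approx(4 * per_d)
        assert sp.net_charge("DDDD", ph=7.0, pka=pka) == pytest.approx(-4.0, abs=0.01)

    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=30),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_over_concatenation(self, a, b):
        assert sp.net_charge(a + b) == pytest.approx(sp.net_charge(a) + sp.net_charge(b))

    @given(seq=st.text(alphabet="DEKRHCY", min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_ph(self, seq):
        charges = [sp.net_charge(seq, ph=ph) for ph in (2.0, 5.0, 7.0, 9.0, 12.0)]
        assert all(x >= y for x, y in zip(charges, charges[1:]))


class TestPercentIdentity:
    def test_identity_case(self):
        assert sp.percent_identity("ACDEFG", "ACDEFG") == pytest.approx(100.0)

    def test_single_substitution(self):
        assert sp.percent_identity("ACDEFG", "ACDEWG") == pytest.approx(100 * 5 / 6, abs=0.01)

    def test_no_matches(self):
        assert sp.percent_identity("AAAA", "CCCC") == pytest.approx(0.0)

    def test_symmetric(self):
        a, b = "MKVLAADEQR", "MKVIGADQQR"
        assert sp.percent_identity(a, b) == pytest.approx(sp.percent_identity(b, a))

    def test_calibrated_mutant_fractions(self):
        _, variants = gen_codon_reference(seed=9)
        ref = variants["variant_000"]
        assert sp.percent_identity(variants["variant_000"], ref) == pytest.approx(100.0)
        assert sp.percent_identity(variants["variant_050"], ref) == pytest.approx(50.0, abs=2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.percent_identity("", "ACD")


class TestCai:
    def test_all_family_maximal_codons_score_one(self):
        orf, _ = gen_codon_reference(seed=3)
        table = sp.codon_frequencies(orf)
        weights = sp.cai_weights(table)
        best = sp.back_translate(sp.translate(orf), table)
        assert sp.cai(best, weights) == pytest.approx(1.0)

    def test_geometric_mean_of_one(self):
        # single informative codon with w = 0.25: GGA (Gly, 4-codon family)
        weights = {"GGA": 0.25}
        assert sp.cai("ATGGGA", weights) == pytest.approx(0.25)

    def test_geometric_mean_of_two(self):
        weights = {"GGA": 0.5, "GCG": 0.125}
        assert sp.cai("GGAGCG", weights) == pytest.approx(0.25)

    def test_cai_never_exceeds_one(self):
        orf, _ = gen_codon_reference(seed=4)
        weights = sp.cai_weights(sp.codon_frequencies(orf))
        assert sp.cai(orf, weights) <= 1.0

    def test_zero_weight_floored(self):
        # codon absent from the reference set gets the 0.01 floor
        assert sp.cai("GGA", {"GGG": 1.0}) == pytest.approx(0.01)

    def test_uninformative_gene_rejected(self):
        with pytest.raises(ValueError):
            sp.cai("ATGTGG", {})  # only Met + Trp: no informative codons


class TestMrnaWindow:
    def test_near_start_offset(self):
        construct = "A" * 200
        assert sp.mrna_window(construct, 100, offset=-4)[:2] == (96, 138)

    def test_upstream_offset(self):
        construct = "A" * 200
        assert sp.mrna_window(construct, 100, offset=-50)[:2] == (50, 92)

    def test_out_of_bounds_reports_overhang(self):
        with pytest.raises(sp.CoordinateError, match=r"-40"):
            sp.mrna_window("A" * 200, 10, offset=-50)

    def test_sequence_slice_matches_coordinates(self):
        construct = "ACGT" * 50
        s, e, seq = sp.mrna_window(construct, 100, offset=-4, length=42)
        assert seq == construct[s:e] and len(seq) == 42


class TestTmFromThermogram:
    def test_constructed_peak(self):
        tg = gen_thermogram(tm=55.0, baseline_slope=0.02, grid_step=0.1)
        assert sp.tm_from_thermogram(tg) == pytest.approx(55.0, abs=0.1)

    def test_global_maximum_of_two_peaks(self):
        t = np.arange(20.0, 80.0, 0.1)
        s = np.exp(-0.5 * ((t - 45) / 2) ** 2) + 2 * np.exp(-0.5 * ((t - 60) / 2) ** 2)
        assert sp.tm_from_thermogram(sp.Thermogram(t, s)) == pytest.approx(60.0, abs=0.1)

    def test_flat_signal_rejected(self):
        t = np.arange(20.0, 80.0, 0.1)
        with pytest.raises(sp.NoTransitionError):
            sp.tm_from_thermogram(sp.Thermogram(t, np.ones_like(t)))

    @pytest.mark.parametrize("slope,intercept", [(0.0, 0.0), (0.5, -3.0), (-0.2, 7.0)])
    def test_invariant_to_affine_baseline(self, slope, intercept):
        t = np.arange(20.0, 80.0, 0.1)
        peak = np.exp(-0.5 * ((t - 52.3) / 2.5) ** 2)
        tg = sp.Thermogram(t, peak + slope * t + intercept)
        assert sp.tm_from_thermogram(tg) == pytest.approx(52.3, abs=0.1)
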