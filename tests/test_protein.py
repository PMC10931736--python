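"""Variant application, translation with explicit selenocysteine recoding,
and the ProtParam-style physicochemical calculators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imf.protein import (
    CdsVariant,
    apply_variant,
    charged_counts,
    gravy,
    instability_index,
    molecular_weight,
    net_charge,
    physchem_report,
    theoretical_pi,
    translate,
)
from imf.protparam_data import AVG_RESIDUE_MASS, WATER_MW

AA20 = "ACDEFGHIKLMNPQRSTVWY"
peptides = st.text(alphabet=AA20, min_size=2, max_size=40)


class TestApplyVariant:
    def test_substitution(self):
        assert apply_variant("GAC", CdsVariant(3, "C", "T")) == "GAT"

    def test_ref_mismatch_reports_observed(self):
        with pytest.raises(ValueError, match="observed G"):
            apply_variant("GAC", CdsVariant(1, "A", "T"))

    def test_position_beyond_cds(self):
        with pytest.raises(ValueError, match="beyond"):
            apply_variant("GAC", CdsVariant(4, "C", "T"))

    def test_position_1146_is_codon_382_base_3(self):
        # the motivating variant lands on a clean codon boundary
        position = 1146
        codon, offset = divmod(position - 1, 3)
        assert (codon + 1, offset + 1) == (382, 3)


class TestTranslate:
    def test_standard_code(self):
        assert translate("GCAGTA") == "AV"

    def test_sec_recoding_explicit(self):
        assert translate("TGA", sec_positions=[1]) == "U"

    def test_unrecoded_internal_stop_errors_with_index(self):
        with pytest.raises(ValueError, match="codon 1"):
            translate("TGAGCA")

    def test_trailing_stop_dropped(self):
        assert translate("GCATAA") == "A"

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible"):
            translate("GCAG")


class TestMolecularWeight:
    def test_diglycine(self):
        assert molecular_weight("GG") == pytest.approx(2 * 57.0519 + 18.0153, abs=1e-6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            molecular_weight("")

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            molecular_weight("GXG")

    def test_matches_biopython_on_standard_residues(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list(AA20), size=rng.integers(5, 60)))
            # the two published average-mass tables differ in the 3rd decimal
            # per residue; agreement is to ~1e-5 relative
            assert molecular_weight(seq) == pytest.approx(
                ProteinAnalysis(seq).molecular_weight(), rel=1e-4
            )

    @given(peptides, peptides)
    @settings(max_examples=100, derandomize=True)
    def test_additivity(self, a, b):
        assert molecular_weight(a + b) == pytest.approx(
            molecular_weight(a) + molecular_weight(b) - WATER_MW, abs=1e-6
        )

    def test_glu_to_sec_delta(self):
        seq = "MKTEEALR"
        mutant = seq.replace("E", "U", 1)
        delta = molecular_weight(mutant) - molecular_weight(seq)
        assert delta == pytest.approx(AVG_RESIDUE_MASS["U"] - AVG_RESIDUE_MASS["E"], abs=1e-9)
        assert delta == pytest.approx(20.92, abs=0.01)


class TestTheoreticalPi:
    def test_acidic_peptide_below_7(self):
        assert theoretical_pi("DDDDDD") < 7.0

    def test_basic_peptide_above_7(self):
        assert theoretical_pi("KKKKKK") > 7.0

    def test_bisection_equals_grid_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            seq = "".join(rng.choice(list(AA20), size=rng.integers(3, 40)))
            grid = np.arange(0.0, 14.0, 0.001)
            charges = np.array([net_charge(seq, ph) for ph in grid])
            root = grid[np.argmin(np.abs(charges))]
            assert theoretical_pi(seq) == pytest.approx(root, abs=0.01)

    def test_no_sidechain_groups_still_defined(self):
        # only termini ionize; pI between the two terminal pKa values
        pi = theoretical_pi("GGG")
        assert 2.34 < pi < 9.69

    @given(peptides)
    @settings(max_examples=60, derandomize=True)
    def test_monotone_under_charged_appends(self, seq):
        pi = theoretical_pi(seq)
        assert theoretical_pi(seq + "K") >= pi - 0.01
        assert theoretical_pi(seq + "D") <= pi + 0.01


class TestInstabilityIndex:
    def test_diglycine_hand_value(self):
        # (10/2) x DIWV(G,G) = 5 x 13.34
        assert instability_index("GG") == pytest.approx(66.7)

    def test_homopolymer_closed_form(self):
        # L-mer homopolymer: (10/L) * (L-1) * DIWV(x, x)
        from Bio.SeqUtils.ProtParamData import DIWV

        for residue, L in (("M", 10), ("G", 7)):
            expected = 10.0 / L * (L - 1) * DIWV[residue][residue]
            assert instability_index(residue * L) == pytest.approx(expected)

    def test_single_residue_errors(self):
        with pytest.raises(ValueError):
            instability_index("G")

    def test_matches_biopython(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = "".join(rng.choice(list(AA20), size=rng.integers(5, 50)))
            assert instability_index(seq) == pytest.approx(
                ProteinAnalysis(seq).instability_index(), abs=0.01
            )


class TestGravy:
    @pytest.mark.parametrize("seq, expected", [("AA", 1.8), ("RR", -4.5)])
    def test_table_values(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected)

    @given(peptides)
    @settings(max_examples=100, derandomize=True)
    def test_bounded(self, seq):
        assert -4.5 <= gravy(seq) <= 4.5

    def test_u_value_configurable(self):
        assert gravy("U", u_value=0.0) == 0.0
        assert gravy("U") == pytest.approx(2.5)


class TestChargedCounts:
    @pytest.mark.parametrize(
        "seq, expected", [("DEDE", (4, 0)), ("GGG", (0, 0)), ("RKDE", (2, 2))]
    )
    def test_counts(self, seq, expected):
        assert charged_counts(seq) == expected

    def test_glu_to_sec_decrements_negatives(self):
        seq = "MDEEKR"
        mutant = seq.replace("E", "U", 1)
        assert charged_counts(seq)[0] - charged_counts(mutant)[0] == 1


class TestEToUSignature:
    """The E->U edit moves every report quantity in a fixed direction."""

    @given(st.text(alphabet=AA20, min_size=5, max_size=60).filter(lambda s: "E" in s))
    @settings(max_examples=60, derandomize=True)
    def test_directional_deltas(self, seq):
        i = seq.index("E")
        mutant = seq[:i] + "U" + seq[i + 1 :]
        assert molecular_weight(mutant) - molecular_weight(seq) == pytest.approx(20.92, abs=0.01)
        assert charged_counts(mutant)[0] == charged_counts(seq)[0] - 1
        assert theoretical_pi(mutant) >= theoretical_pi(seq) - 1e-9
        assert gravy(mutant) > gravy(seq)


def test_physchem_report_roundtrip():
    report = physchem_report("MKTEEALRDDWK")
    d = report.as_dict()
    assert d["length"] == 12
    assert report.unstable is (report.instability > 40)
    assert 0 < d["theoretical_pi"] < 14
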