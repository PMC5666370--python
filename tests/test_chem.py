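"""Mass-engine unit and property tests.

The independent oracle for peptide masses is pyteomics (its own atomic
constants and composition logic); the two internal routes (formula
arithmetic vs frozen residue-mass literals) are additionally required to
agree with each other to 1e-6 Da.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyt_mass

from venompep import chem

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=40)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


class TestElementalFormula:
    def test_parse_hill_round_trip(self):
        f = chem.ElementalFormula.parse("C95H152N24O23S2")
        assert f.counts == {"C": 95, "H": 152, "N": 24, "O": 23, "S": 2}
        assert f.hill() == "C95H152N24O23S2"

    def test_equality_independent_of_construction(self):
        a = chem.ElementalFormula({"C": 2, "H": 4}) + chem.ElementalFormula({"O": 1})
        b = chem.ElementalFormula({"O": 1, "C": 2, "H": 4, "S": 0})
        assert a == b and hash(a) == hash(b)

    def test_arithmetic_commutes_and_restores(self):
        a = chem.ElementalFormula.parse("C3H5NO")
        b = chem.ElementalFormula.parse("C6H12N2O")
        c = chem.ElementalFormula.parse("H2O")
        assert a + b == b + a
        assert (a + b) + c == a + (b + c)
        assert (a + b) - b == a

    def test_subtraction_below_zero_is_error(self):
        a = chem.ElementalFormula.parse("C2H3NO")
        with pytest.raises(ValueError, match="negative"):
            a - chem.ElementalFormula.parse("S1")

    def test_unknown_element_named_in_error(self):
        f = chem.ElementalFormula.parse("C2Zr3")
        with pytest.raises(KeyError, match="Zr"):
            chem.formula_mass(f)

    def test_empty_formula_has_zero_mass(self):
        assert chem.formula_mass(chem.ElementalFormula()) == 0.0

    def test_water_mass(self):
        assert chem.formula_mass(chem.WATER) == pytest.approx(18.0106, abs=5e-5)


class TestPeptideFormula:
    @pytest.mark.parametrize(
        "seq, c_term, multimer, expected",
        [
            ("GILDWGKKVMDWIKDKM", "amide", "monomer", "C95H152N24O23S2"),
            ("GVKELFGKAWGLVKKHLPKACGLLGYVKQ", "free_acid", "disulfide_homodimer", "C300H484N78O68S2"),
            ("G", "free_acid", "monomer", "C2H5N1O2"),
        ],
    )
    def test_known_compositions(self, seq, c_term, multimer, expected):
        formula = chem.peptide_formula(seq, c_term, multimer=multimer)
        assert formula == chem.ElementalFormula.parse(expected)

    def test_nonstandard_letters_rejected(self):
        for letter in "BZXUO":
            with pytest.raises(ValueError, match="unsupported residue"):
                chem.peptide_formula(f"GK{letter}A")

    def test_met_oxide_requires_methionine(self):
        with pytest.raises(ValueError, match="requires residue M"):
            chem.peptide_formula("GAK", residue_mods=[(0, chem.MET_OXIDE)])
        ox = chem.peptide_formula("GMK", residue_mods=[(1, chem.MET_OXIDE)])
        plain = chem.peptide_formula("GMK")
        assert ox == plain.shift({"O": 1})

    def test_homodimer_needs_cysteine(self):
        with pytest.raises(ValueError, match="cysteine"):
            chem.peptide_formula("GAK", multimer="disulfide_homodimer")


class TestPeptideMass:
    def test_against_pyteomics_oracle(self):
        for seq in ["GWGSLFK", "GILDWGKKVMDWIKDKM", "KIKWGKIFKKGGKLIGKTALEAAANAAASEAISAMASQNEK"]:
            ours = chem.peptide_mass(seq)
            ref = pyt_mass.calculate_mass(sequence=seq, monoisotopic=True)
            assert ours == pytest.approx(ref, abs=1e-3)

    def test_amide_against_pyteomics_composition(self):
        comp = pyt_mass.Composition(sequence="KVMDWLKDKM")
        comp["O"] -= 1
        comp["N"] += 1
        comp["H"] += 1
        ref = pyt_mass.calculate_mass(composition=comp, monoisotopic=True)
        assert chem.peptide_mass("KVMDWLKDKM", "amide") == pytest.approx(ref, abs=1e-3)

    def test_average_mass_exceeds_monoisotopic(self):
        seq = "GILDWGKKVMDWIKDKM"
        assert chem.peptide_mass(seq, kind="average") > chem.peptide_mass(seq)

    @given(seq=sequences)
    def test_formula_and_residue_routes_agree(self, seq):
        via_formula = chem.formula_mass(chem.peptide_formula(seq))
        via_residues = chem.peptide_mass(seq)
        assert abs(via_formula - via_residues) < 1e-6

    @given(seq=sequences)
    def test_amide_shift_is_constant(self, seq):
        delta = chem.peptide_mass(seq, "amide") - chem.peptide_mass(seq)
        assert delta == pytest.approx(-0.98402, abs=1e-5)

    @given(seq=sequences)
    def test_homodimer_is_two_monomers_minus_two_hydrogens(self, seq):
        seq = seq + "C"
        dimer = chem.peptide_mass(seq, multimer="disulfide_homodimer")
        mono = chem.peptide_mass(seq)
        assert dimer == pytest.approx(2 * mono - 2.01565, abs=1e-5)

    @given(seq=sequences)
    def test_leucine_isoleucine_equivalence(self, seq):
        swapped = seq.replace("L", "i").replace("I", "L").replace("i", "I")
        assert chem.peptide_formula(seq) == chem.peptide_formula(swapped)
        assert chem.peptide_mass(seq) == pytest.approx(chem.peptide_mass(swapped), abs=1e-12)

    def test_modification_apply_revert_round_trip(self):
        f = chem.peptide_formula("GMK")
        for mod in (chem.AMIDATION, chem.MET_OXIDE):
            assert mod.revert(mod.apply(f)) == f


class TestFormulaReconciliation:
    def test_consistent_pair_passes(self):
        check = chem.check_reported_formula("GILDWGKKVMDWIKDKM", "amide", "C95H152N24O23S2")
        assert check.consistent and check.note == ""

    def test_terminal_state_mixup_is_flagged_not_silently_resolved(self):
        # an amidated sequence paired with its free-acid formula: both masses
        # must be reported and the pair flagged
        check = chem.check_reported_formula("IWGALLGTLIPAITSAIQ", "amide", "C87H144N20O23")
        assert not check.consistent
        assert check.reported_mass == pytest.approx(1837.071, abs=5e-4)
        assert check.sequence_mass == pytest.approx(1836.087, abs=5e-4)
        assert "differs" in check.note

    def test_residue_table_masses_match_their_formulas(self):
        table = chem.STANDARD_AA
        for letter in table.letters:
            assert table.mass(letter) == pytest.approx(
                chem.formula_mass(table.formula(letter)), abs=1e-9
            )
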