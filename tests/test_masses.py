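import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oglyco.masses import (
    CORE_GLYCANS,
    HEXNAC_MASS,
    PROTON,
    GlycanComposition,
    ModificationSpec,
    OxoniumTable,
    OXIDATION_M,
    fragment_ions,
    peptide_mass,
    precursor_mz,
)

from oracles import by_ions_oracle, peptide_mass_oracle

SEQ = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


class TestPeptideMass:
    def test_single_glycine(self):
        assert peptide_mass("G") == pytest.approx(75.03203, abs=2e-5)

    def test_core1_glycopeptide(self):
        mods = [(1, GlycanComposition(hex=1, hexnac=1))]
        assert peptide_mass("TKLSPNR", mods) == pytest.approx(1179.59828, abs=2e-5)

    @given(seq=SEQ)
    def test_matches_independent_summation(self, seq):
        assert peptide_mass(seq) == pytest.approx(peptide_mass_oracle(seq), abs=1e-3)

    @given(seq=SEQ, n_ox=st.integers(0, 3))
    def test_modification_additivity(self, seq, n_ox):
        mods = [(1, OXIDATION_M)] * n_ox + [(len(seq), GlycanComposition(hexnac=2))]
        delta = sum(m.delta_mass for _, m in mods)
        assert peptide_mass(seq, mods) - peptide_mass(seq) == pytest.approx(delta, abs=1e-9)
        # order of the mod list never changes the mass
        assert peptide_mass(seq, mods[::-1]) == peptide_mass(seq, mods)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match=r"'B' at position 2"):
            peptide_mass("ABC")

    def test_bad_mod_position_rejected(self):
        with pytest.raises(ValueError, match="position"):
            peptide_mass("AG", [(3, OXIDATION_M)])


class TestGlycanComposition:
    @pytest.mark.parametrize(
        "comp,expected",
        [
            (GlycanComposition(hex=1, hexnac=1), 365.13219),
            (GlycanComposition(hexnac=1), 203.07937),
            (GlycanComposition(hex=1, hexnac=2), 568.21156),
            (GlycanComposition(hex=2, hexnac=2), 730.26438),
        ],
    )
    def test_core_glycan_deltas(self, comp, expected):
        assert comp.delta_mass == pytest.approx(expected, abs=1e-4)

    @given(h=st.integers(0, 4), n=st.integers(0, 4), s=st.integers(0, 2), f=st.integers(0, 2))
    def test_delta_is_linear_in_counts(self, h, n, s, f):
        if h + n + s + f == 0:
            with pytest.raises(ValueError):
                GlycanComposition(hex=h, hexnac=n, neuac=s, fuc=f)
            return
        comp = GlycanComposition(hex=h, hexnac=n, neuac=s, fuc=f)
        expected = 162.05282 * h + 203.07937 * n + 291.09542 * s + 146.05791 * f
        assert comp.delta_mass == pytest.approx(expected, abs=1e-4)

    def test_string_round_trip(self):
        for comp in CORE_GLYCANS:
            assert GlycanComposition.parse(str(comp)) == comp


class TestPrecursorMz:
    def test_charge_one_adds_proton(self):
        assert precursor_mz(1000.0, 1) == pytest.approx(1001.00728, abs=1e-5)

    def test_core1_glycopeptide_doubly_charged(self):
        assert precursor_mz(1179.59828, 2) == pytest.approx(590.80642, abs=1e-5)

    @given(mass=st.floats(100, 5000), z=st.integers(1, 6))
    def test_inversion(self, mass, z):
        assert precursor_mz(mass, z) * z - z * PROTON == pytest.approx(mass, rel=1e-12)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            precursor_mz(1000.0, 0)


class TestFragmentIons:
    def test_b1_of_ag(self):
        ions = dict(fragment_ions("AG", kinds=("b",), charges=(1,)))
        assert ions["b1+"] == pytest.approx(72.04439, abs=2e-5)

    @pytest.mark.parametrize("z", [1, 2, 3])
    def test_y1_minus_y0_is_hexnac_over_charge(self, z):
        ions = dict(fragment_ions("TKLSPNR", kinds=("Y0", "Y1"), charges=(z,)))
        delta = ions[f"Y1{'+' * z}"] - ions[f"Y0{'+' * z}"]
        assert delta == pytest.approx(203.07937 / z, abs=1e-4)

    def test_full_by_set_matches_independent_enumeration(self):
        got = sorted(mz for _, mz in fragment_ions("TKLSPNR", kinds=("b", "y"), charges=(1, 2)))
        expected = sorted(by_ions_oracle("TKLSPNR", charges=(1, 2)))
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=1e-4)

    def test_glycans_excluded_from_backbone_ions(self):
        plain = fragment_ions("TKLSPNR", kinds=("b", "y"), charges=(1,))
        glyco = fragment_ions(
            "TKLSPNR", [(1, GlycanComposition(hex=1, hexnac=1))], kinds=("b", "y"), charges=(1,)
        )
        assert plain == glyco

    def test_glycans_retained_on_request(self):
        comp = GlycanComposition(hexnac=1)
        shifted = dict(
            fragment_ions("TKLSPNR", [(1, comp)], kinds=("b",), charges=(1,), retain_glycans=True)
        )
        plain = dict(fragment_ions("TKLSPNR", kinds=("b",), charges=(1,)))
        assert shifted["b1+"] == pytest.approx(plain["b1+"] + comp.delta_mass, abs=1e-6)

    def test_non_glycan_mods_included_in_backbone(self):
        shifted = dict(fragment_ions("MAG", [(1, OXIDATION_M)], kinds=("b",), charges=(1,)))
        plain = dict(fragment_ions("MAG", kinds=("b",), charges=(1,)))
        assert shifted["b1+"] == pytest.approx(plain["b1+"] + OXIDATION_M.delta_mass, abs=1e-6)

    def test_empty_kinds_rejected(self):
        with pytest.raises(ValueError):
            fragment_ions("AG", kinds=())


class TestOxoniumTable:
    def test_default_contents(self):
        expected = {
            126.0550, 138.0550, 144.0655, 168.0655, 186.0761,
            204.0867, 163.0601, 274.0921, 292.1027, 366.1395,
        }
        table = OxoniumTable()
        assert {round(mz, 4) for _, mz in table.ions} == expected
        assert table.mandatory_mz == pytest.approx(204.0867)

    def test_tsv_override(self, tmp_path):
        path = tmp_path / "oxonium.tsv"
        path.write_text("HexNAc\t204.0867\nHex\t163.0601\n")
        table = OxoniumTable.from_tsv(path)
        assert len(table.ions) == 2

    def test_table_without_mandatory_ion_rejected(self):
        with pytest.raises(ValueError):
            OxoniumTable(ions=(("Hex", 163.0601),))
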