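import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oglyco.digestion import (
    PeptideEntry,
    ProteinRecord,
    build_search_space,
    internal_st_count,
    make_decoys,
    operator_digest,
    read_fasta,
    tryptic_digest,
    write_fasta,
)

from oracles import search_space_oracle

PROT = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


class TestTrypticDigest:
    def test_two_site_example(self):
        got = set(tryptic_digest("MAGTKLSPNR", 2))
        assert got == {("MAGTK", 1, 0), ("LSPNR", 6, 0), ("MAGTKLSPNR", 1, 1)}

    def test_no_cleavage_sites_returns_whole_sequence(self):
        assert tryptic_digest("AGAGAG", 2) == [("AGAGAG", 1, 0)]

    def test_every_residue_a_cut_site(self):
        assert set(tryptic_digest("KKK", 0)) == {("K", 1, 0), ("K", 2, 0), ("K", 3, 0)}

    def test_proline_rule_suppresses_cleavage(self):
        # cleavage before proline happens by default; the optional rule stops it
        assert any(p == "MAGK" for p, _, _ in tryptic_digest("MAGKPLR", 0))
        assert all(
            p != "MAGK" for p, _, _ in tryptic_digest("MAGKPLR", 0, proline_rule=True)
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("", 2)

    @given(seq=PROT)
    def test_products_end_and_start_at_cleavage_boundaries(self, seq):
        for pep, start, missed in tryptic_digest(seq, 2):
            end = start - 1 + len(pep)
            assert start == 1 or seq[start - 2] in "KR"
            assert end == len(seq) or seq[end - 1] in "KR"
            assert sum(1 for aa in pep[:-1] if aa in "KR") == missed <= 2


class TestOperatorDigest:
    def test_two_site_example(self):
        frags = {f for f, _, _ in operator_digest("MAGTKLSPNR", 5)}
        assert frags == {"MAG", "TKL", "SPNR", "MAGTKL", "TKLSPNR", "MAGTKLSPNR"}

    def test_no_st_returns_input(self):
        assert operator_digest("AAAA", 5) == [("AAAA", 1, 0)]

    def test_nterm_st_is_not_a_cut_site(self):
        assert operator_digest("TAAA", 5) == [("TAAA", 1, 0)]

    @given(seq=PROT)
    def test_counting_identity(self, seq):
        # with an unconstrained budget, k internal sites yield (k+1)(k+2)/2 fragments
        k = internal_st_count(seq)
        frags = operator_digest(seq, max_missed=k)
        assert len(frags) == (k + 1) * (k + 2) // 2

    @given(seq=PROT, budget=st.integers(0, 5))
    def test_budget_monotonicity(self, seq, budget):
        small = {(f, o) for f, o, _ in operator_digest(seq, budget)}
        large = {(f, o) for f, o, _ in operator_digest(seq, budget + 1)}
        assert small <= large


class TestBuildSearchSpace:
    def test_two_stage_example(self):
        entries = build_search_space([ProteinRecord("P1", "MAGTKLSPNR")])
        assert {e.sequence for e in entries} == {"TKLSPNR", "MAGTKL", "MAGTKLSPNR"}

    def test_no_st_protein_yields_nothing(self):
        assert build_search_space([ProteinRecord("P1", "A" * 30)]) == []

    def test_duplicate_protein_merges_parents(self):
        prots = [ProteinRecord("P1", "MAGTKLSPNR"), ProteinRecord("P2", "MAGTKLSPNR")]
        entries = build_search_space(prots)
        assert {e.sequence for e in entries} == {"TKLSPNR", "MAGTKL", "MAGTKLSPNR"}
        for e in entries:
            assert {acc for acc, _ in e.parents} == {"P1", "P2"}

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_search_space([])

    @given(seq=PROT)
    def test_equivalence_with_substring_oracle(self, seq):
        entries = build_search_space([ProteinRecord("P1", seq)])
        assert {e.sequence for e in entries} == search_space_oracle(seq)

    @given(seq=PROT)
    def test_entries_respect_filters_and_provenance(self, seq):
        for e in build_search_space([ProteinRecord("P1", seq)]):
            assert 6 <= len(e.sequence) <= 46
            assert any(aa in "ST" for aa in e.sequence)
            assert e.operator_mc == internal_st_count(e.sequence) <= 5
            assert e.tryptic_mc <= 2
            for _, start in e.parents:
                assert seq[start - 1 : start - 1 + len(e.sequence)] == e.sequence

    @given(seq=PROT, tmc=st.integers(0, 2), omc=st.integers(0, 4))
    def test_budget_monotonicity(self, seq, tmc, omc):
        small = {e.sequence for e in build_search_space([ProteinRecord("P", seq)], tryp_mc=tmc, oper_mc=omc)}
        larger = {e.sequence for e in build_search_space([ProteinRecord("P", seq)], tryp_mc=tmc + 1, oper_mc=omc + 1)}
        assert small <= larger


class TestDecoys:
    PROTS = [ProteinRecord(f"P{i}", "MAGTKLSPNRWDECYHQVIF"[: 8 + i]) for i in range(5)]

    def test_deterministic_for_fixed_seed(self):
        a = make_decoys(self.PROTS, seed=7)
        b = make_decoys(self.PROTS, seed=7)
        assert [d.sequence for d in a] == [d.sequence for d in b]

    def test_length_and_composition_preserved(self):
        for target, decoy in zip(self.PROTS, make_decoys(self.PROTS, seed=7)):
            assert decoy.accession == "DECOY_" + target.accession
            assert decoy.is_decoy
            assert sorted(decoy.sequence) == sorted(target.sequence)

    def test_seed_change_alters_some_sequence(self):
        a = make_decoys(self.PROTS, seed=7)
        b = make_decoys(self.PROTS, seed=8)
        assert any(x.sequence != y.sequence for x, y in zip(a, b))

    def test_preserve_kr_keeps_cleavage_sites(self):
        decoys = make_decoys(self.PROTS, seed=7, preserve_kr=True)
        for target, decoy in zip(self.PROTS, decoys):
            kr_t = [i for i, aa in enumerate(target.sequence) if aa in "KR"]
            kr_d = [i for i, aa in enumerate(decoy.sequence) if aa in "KR"]
            assert kr_t == kr_d


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        prots = [
            ProteinRecord("P1", "MAGTKLSPNR"),
            ProteinRecord("DECOY_P1", "RNPSLKTGAM", is_decoy=True),
        ]
        path = tmp_path / "db.fasta"
        write_fasta(prots, path)
        back = read_fasta(path)
        assert [(p.accession, p.sequence, p.is_decoy) for p in back] == [
            (p.accession, p.sequence, p.is_decoy) for p in prots
        ]

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">P1\nMAGTK\n>P1\nLSPNR\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)
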