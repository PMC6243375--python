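import math

import numpy as np
import pytest

from oglyco.digestion import ProteinRecord, build_search_space
from oglyco.masses import GlycanComposition, fragment_ions, peptide_mass, precursor_mz
from oglyco.search import (
    ModsConfig,
    SearchSpaceIndex,
    assign_fdr,
    enumerate_modified_peptides,
    filter_psms,
    generate_candidates,
    localize_sites,
    report_filter,
    score_psm,
    search_spectra,
)
from oglyco.spectra import Spectrum

from conftest import make_psm
from oracles import binomial_tail_oracle

CORE1 = GlycanComposition(hex=1, hexnac=1)


def spectrum_for(sequence, placements=(), charge=2, extra=(), scan_id="s1", run="r1"):
    """Perfect spectrum of a modified peptide: all theoretical ions, no noise."""
    theo = [mz for _, mz in fragment_ions(sequence, placements, charges=(1, 2))]
    mzs = sorted(theo) + list(extra)
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor_mz(peptide_mass(sequence, placements), charge),
        precursor_charge=charge,
        mz=np.array(mzs),
        intensity=np.full(len(mzs), 100.0),
        source_run=run,
    )


@pytest.fixture(scope="module")
def toy_index():
    entries = build_search_space([ProteinRecord("P1", "MAGTKLSPNR")])
    return SearchSpaceIndex(entries, ModsConfig())


class TestCandidateGeneration:
    def test_core1_glycoform_found_at_its_precursor(self, toy_index):
        s = spectrum_for("TKLSPNR", [(1, CORE1)], charge=2)
        forms = {
            (c.sequence, str(c.glycan_composition() or ""))
            for c, z in generate_candidates(s, toy_index)
        }
        assert ("TKLSPNR", "Hex(1)HexNAc(1)") in forms

    def test_empty_search_space_yields_nothing(self):
        idx = SearchSpaceIndex([], ModsConfig())
        s = spectrum_for("TKLSPNR", [(1, CORE1)])
        assert generate_candidates(s, idx) == []

    def test_tightening_tolerance_never_adds_candidates(self, toy_index):
        s = spectrum_for("TKLSPNR", [(1, CORE1)])
        wide = {(id(c), z) for c, z in generate_candidates(s, toy_index, prec_tol_ppm=10)}
        narrow = {(id(c), z) for c, z in generate_candidates(s, toy_index, prec_tol_ppm=1)}
        assert narrow <= wide

    def test_unknown_charge_tries_range(self, toy_index):
        s = spectrum_for("TKLSPNR", [(1, CORE1)], charge=2)
        s.precursor_charge = None
        forms = {c.sequence for c, z in generate_candidates(s, toy_index, charges=(2, 3))}
        assert "TKLSPNR" in forms

    def test_placement_cap_respected(self, toy_index):
        for form in toy_index.forms:
            n_var = sum(
                1
                for _, m in form.placements
                if isinstance(m, GlycanComposition) or m.mode == "variable"
            )
            assert n_var <= toy_index.mods.max_var_mods

    def test_glycans_sit_on_nterminal_st_first(self):
        entries = build_search_space([ProteinRecord("P1", "MAGTKLSPNR")])
        entry = next(e for e in entries if e.sequence == "TKLSPNR")
        single = [
            f
            for f in enumerate_modified_peptides(entry, ModsConfig())
            if len(f.glycan_placements) == 1
        ]
        assert single and all(f.glycan_placements[0][0] == 1 for f in single)


class TestScore:
    def test_zero_matches_scores_zero(self):
        entry = build_search_space([ProteinRecord("P1", "MAGTKLSPNR")])
        cand = SearchSpaceIndex(entry, ModsConfig()).forms[0]
        s = Spectrum("s", 500.0, 2, np.array([1500.0, 1600.0]), np.array([1.0, 1.0]))
        assert score_psm(s, cand) == 0.0

    def test_tiny_spectrum_scores_zero(self):
        entry = build_search_space([ProteinRecord("P1", "MAGTKLSPNR")])
        cand = SearchSpaceIndex(entry, ModsConfig()).forms[0]
        s = Spectrum("s", 500.0, 2, np.array([204.0867]), np.array([1.0]))
        assert score_psm(s, cand) == 0.0

    def test_matches_independent_binomial_tail(self, toy_index):
        cand = next(
            f
            for f in toy_index.forms
            if f.sequence == "TKLSPNR" and str(f.glycan_composition() or "") == "Hex(1)HexNAc(1)"
        )
        s = spectrum_for("TKLSPNR", cand.placements, extra=(1500.0, 1600.0, 1700.0))
        theo = fragment_ions(cand.sequence, cand.placements, charges=(1, 2))
        n = len(theo)
        tol = 20e-6
        k = len(
            {
                i
                for i, (_, mz) in enumerate(theo)
                if np.min(np.abs(s.mz - mz)) <= mz * tol
            }
        )
        median = float(np.median(s.mz))
        p = min(max(s.n_peaks * 2 * (median * tol) / (s.mz[-1] - s.mz[0]), 1e-6), 0.5)
        expected = -math.log10(binomial_tail_oracle(k, n, p))
        assert score_psm(s, cand) == pytest.approx(expected, abs=1e-9)

    def test_self_match_dominates_shuffled_candidates(self, rng):
        # perfect spectra of their own peptide must outscore an equal-length shuffle
        entries = build_search_space(
            [ProteinRecord("P1", "MAGTKLSPNRWDECYHQVIFSTKGGR" * 2)]
        )
        idx = SearchSpaceIndex(entries, ModsConfig(variable=(CORE1,)))
        cands = [f for f in idx.forms if len(f.glycan_placements) == 1]
        wins = trials = 0
        for _ in range(100):
            cand = cands[rng.integers(len(cands))]
            s = spectrum_for(cand.sequence, cand.placements)
            shuffled = "".join(rng.permutation(list(cand.sequence)))
            if shuffled == cand.sequence:
                continue
            from oglyco.digestion import PeptideEntry
            from oglyco.search import ModifiedPeptide

            rival_entry = PeptideEntry(sequence=shuffled, parents={("X", 1)})
            rival = ModifiedPeptide(
                entry=rival_entry,
                placements=cand.placements,
                total_mass=cand.total_mass,
            )
            trials += 1
            wins += int(score_psm(s, cand) > score_psm(s, rival))
        assert trials > 50 and wins == trials


class TestAssignFdr:
    def test_hand_computed_running_minimum(self):
        labels = [False, False, True, False, True]  # T,T,D,T,D by rank
        psms = [
            make_psm(scan_id=f"s{i}", score=10.0 - i, is_decoy=d)
            for i, d in enumerate(labels)
        ]
        ranked = assign_fdr(psms)
        expected = [0.0, 0.0, 1 / 3, 1 / 3, 2 / 3]
        assert [p.q_value for p in ranked] == pytest.approx(expected)

    def test_all_targets_have_zero_q(self):
        psms = [make_psm(scan_id=f"s{i}", score=float(i)) for i in range(5)]
        assert all(p.q_value == 0.0 for p in assign_fdr(psms))

    def test_appending_worst_decoy_never_decreases_q(self):
        base = [
            make_psm(scan_id=f"s{i}", score=10.0 - i, is_decoy=(i == 2)) for i in range(5)
        ]
        q_before = {p.scan_id: p.q_value for p in assign_fdr([p for p in base])}
        extended = base + [make_psm(scan_id="worst", score=0.1, is_decoy=True)]
        q_after = {p.scan_id: p.q_value for p in assign_fdr(extended)}
        for scan, q in q_before.items():
            assert q_after[scan] >= q - 1e-12

    def test_q_monotone_non_increasing_in_score(self, rng):
        psms = [
            make_psm(scan_id=f"s{i}", score=float(rng.uniform(0, 10)), is_decoy=bool(rng.random() < 0.3))
            for i in range(50)
        ]
        ranked = assign_fdr(psms)
        for a, b in zip(ranked, ranked[1:]):
            assert a.score >= b.score
            assert a.q_value <= b.q_value

    def test_empty_list(self):
        assert assign_fdr([]) == []

    def test_filter_keeps_targets_at_threshold(self):
        psms = assign_fdr(
            [make_psm(scan_id=f"s{i}", score=10.0 - i, is_decoy=(i == 4)) for i in range(5)]
        )
        kept = filter_psms(psms, fdr=0.01)
        assert all(not p.is_decoy and p.q_value <= 0.01 for p in kept)


class TestReportFilter:
    def test_fetuin_partition_specificity(self):
        site_specific = [make_psm(scan_id=f"g{i}") for i in range(193)]
        other = [make_psm(scan_id=f"o{i}", glycan=None) for i in range(77)]
        kept, summary = report_filter(site_specific + other)
        assert len(kept) == 193
        assert summary.specificity == 71.5

    def test_zero_of_n(self):
        psms = [make_psm(scan_id=f"o{i}", oxonium_passed=False) for i in range(10)]
        _, summary = report_filter(psms)
        assert summary.specificity == 0.0

    def test_n_of_n(self):
        psms = [make_psm(scan_id=f"g{i}") for i in range(10)]
        _, summary = report_filter(psms)
        assert summary.specificity == 100.0

    def test_empty_input_undefined(self):
        _, summary = report_filter([])
        assert summary.specificity is None

    @pytest.mark.parametrize("a,b", [(3, 7), (1, 0), (50, 13)])
    def test_arbitrary_partition_exact(self, a, b):
        psms = [make_psm(scan_id=f"g{i}") for i in range(a)]
        psms += [make_psm(scan_id=f"o{i}", glycan=None) for i in range(b)]
        _, summary = report_filter(psms)
        assert summary.specificity == round(100.0 * a / (a + b), 1)

    def test_site_specific_requires_all_three_conditions(self):
        no_glycan = make_psm(glycan=None)
        no_oxonium = make_psm(oxonium_passed=False)
        no_st = make_psm(sequence="LKAGNR")
        assert not no_glycan.is_site_specific
        assert not no_oxonium.is_site_specific
        assert not no_st.is_site_specific
        assert make_psm().is_site_specific


class TestLocalizeSites:
    PROT = "A" * 295 + "TKLSPNR" + "A" * 20

    def test_peptide_start_becomes_site_position(self):
        psm = make_psm(parents={("P1", 296)})
        sites = localize_sites([psm], {"P1": self.PROT})
        assert len(sites) == 1
        assert (sites[0].accession, sites[0].position, sites[0].residue) == ("P1", 296, "T")
        assert sites[0].compositions == {"Hex(1)HexNAc(1)": 1}

    def test_two_runs_aggregate_into_one_record(self):
        a = make_psm(parents={("P1", 296)}, run="tumor", scan_id="a")
        b = make_psm(parents={("P1", 296)}, run="normal", scan_id="b")
        sites = localize_sites([a, b], {"P1": self.PROT})
        assert len(sites) == 1
        assert sites[0].psm_counts == {"tumor": 1, "normal": 1}

    def test_shared_parents_flagged_and_counted_on_each(self):
        psm = make_psm(parents={("P1", 296), ("P2", 1)})
        sites = localize_sites([psm], {"P1": self.PROT, "P2": "TKLSPNR" + "A" * 10})
        assert {s.accession for s in sites} == {"P1", "P2"}
        assert all(s.shared for s in sites)


class TestSearchSpectra:
    def test_one_best_per_scan(self):
        prot = ProteinRecord("P1", "MAGTKLSPNR")
        entries = build_search_space([prot])
        idx = SearchSpaceIndex(entries, ModsConfig())
        spectra = [
            spectrum_for("TKLSPNR", ((1, CORE1),), scan_id="s1"),
            spectrum_for("TKLSPNR", ((1, CORE1),), scan_id="s2"),
        ]
        psms = search_spectra(spectra, idx)
        scans = [p.scan_id for p in psms]
        assert len(scans) == len(set(scans)) == 2
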