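"""Glycopeptide spectrum matching, target-decoy FDR and report filtering.

Candidates are modified peptides from the dual-digestion search space whose
precursor m/z lies within tolerance of the spectrum's. Matches are scored
with a binomial-tail matched-peak statistic; PSM-level q-values come from
target-decoy competition; the report filter keeps site-specific
O-glycopeptide PSMs (N-terminal S/T, a glycan placement, and a passing
oxonium verdict) and computes the enrichment specificity.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .digestion import PeptideEntry, ProteinRecord
from .masses import (
    CARBAMIDOMETHYL_C,
    CORE_GLYCANS,
    GUANIDINATION_K,
    OXIDATION_M,
    GlycanComposition,
    Modification,
    ModificationSpec,
    fragment_ions,
    is_glycan,
    neutral_mass,
    peptide_mass,
    precursor_mz,
)
from .spectra import OxoniumVerdict, Spectrum, match_peaks
from .sites import SiteRecord


@dataclass(frozen=True)
class ModsConfig:
    """Fixed and variable modification sets plus the placement cap."""

    fixed: tuple[ModificationSpec, ...] = (CARBAMIDOMETHYL_C,)
    variable: tuple[Modification, ...] = (OXIDATION_M, GUANIDINATION_K) + CORE_GLYCANS
    max_var_mods: int = 4

    def glycans(self) -> tuple[GlycanComposition, ...]:
        return tuple(m for m in self.variable if is_glycan(m))


@dataclass(frozen=True)
class ModifiedPeptide:
    """A search-space peptide with a concrete modification placement."""

    entry: PeptideEntry
    placements: tuple[tuple[int, Modification], ...]
    total_mass: float

    @property
    def sequence(self) -> str:
        return self.entry.sequence

    @property
    def glycan_placements(self) -> tuple[tuple[int, GlycanComposition], ...]:
        return tuple((p, m) for p, m in self.placements if is_glycan(m))

    @property
    def glycan_mass_total(self) -> float:
        return sum(m.delta_mass for _, m in self.glycan_placements)

    def glycan_composition(self) -> GlycanComposition | None:
        """Total glycan composition over all placements, or None if unglycosylated."""
        glycans = self.glycan_placements
        if not glycans:
            return None
        return GlycanComposition(
            hex=sum(g.hex for _, g in glycans),
            hexnac=sum(g.hexnac for _, g in glycans),
            neuac=sum(g.neuac for _, g in glycans),
            fuc=sum(g.fuc for _, g in glycans),
        )

    def mods_string(self) -> str:
        parts = []
        for pos, mod in self.placements:
            name = str(mod) if is_glycan(mod) else mod.name
            parts.append(f"{pos}:{name}")
        return ";".join(parts)


@dataclass
class GlycoPSM:
    """One spectrum <-> modified-peptide match."""

    scan_id: str
    source_run: str
    peptide: ModifiedPeptide
    charge: int
    precursor_mz: float
    score: float
    is_decoy: bool
    oxonium_passed: bool
    q_value: float = math.nan

    @property
    def nterm_st(self) -> bool:
        return self.peptide.entry.nterm_st

    @property
    def has_glycan(self) -> bool:
        return bool(self.peptide.glycan_placements)

    @property
    def is_site_specific(self) -> bool:
        return self.has_glycan and self.oxonium_passed and self.nterm_st


def enumerate_modified_peptides(
    entry: PeptideEntry, mods: ModsConfig
) -> list[ModifiedPeptide]:
    """All modification states of ``entry``: fixed mods applied exhaustively,
    then variable placements up to ``max_var_mods`` in total.

    Non-glycan variable mods (which shift b/y ions) are enumerated over every
    eligible residue. Glycans are enumerated as composition multisets, not
    per-position placements: under HCD lability a glycan's position affects
    no theoretical ion (b/y exclude glycans; Y0/Y1 and the precursor depend
    only on the total), so each multiset is anchored canonically on the
    N-terminal-most S/T residues — matching the reporting convention that a
    single glycan sits on the cleavage-defining N-terminal site.
    """
    seq = entry.sequence
    base: list[tuple[int, Modification]] = []
    for spec in mods.fixed:
        for i, aa in enumerate(seq, start=1):
            if aa in spec.targets:
                base.append((i, spec))

    st_positions = [i for i, aa in enumerate(seq, start=1) if aa in "ST"]
    glycans = [m for m in mods.variable if is_glycan(m)]
    # applicable non-glycan variable mods per position, N-terminus first
    options: list[tuple[int, list[Modification]]] = []
    for i, aa in enumerate(seq, start=1):
        here = [m for m in mods.variable if not is_glycan(m) and aa in m.targets]
        if here:
            options.append((i, here))

    base_mass = peptide_mass(seq, base)
    out: list[ModifiedPeptide] = []
    chosen: list[tuple[int, Modification]] = []

    def add_glycoforms(budget: int, mass: float) -> None:
        backbone = tuple(base + chosen)
        out.append(ModifiedPeptide(entry=entry, placements=backbone, total_mass=mass))
        max_g = min(budget, len(st_positions))
        for g in range(1, max_g + 1):
            for combo in itertools.combinations_with_replacement(glycans, g):
                placements = backbone + tuple(
                    (st_positions[j], gl) for j, gl in enumerate(combo)
                )
                out.append(
                    ModifiedPeptide(
                        entry=entry,
                        placements=placements,
                        total_mass=mass + sum(gl.delta_mass for gl in combo),
                    )
                )

    def recurse(idx: int, budget: int, mass: float) -> None:
        add_glycoforms(budget, mass)
        if budget == 0:
            return
        for j in range(idx, len(options)):
            pos, here = options[j]
            for m in here:
                chosen.append((pos, m))
                recurse(j + 1, budget - 1, mass + m.delta_mass)
                chosen.pop()

    recurse(0, mods.max_var_mods, base_mass)
    return out


class SearchSpaceIndex:
    """Mass-sorted index over all modification states of a search space."""

    def __init__(self, entries: Sequence[PeptideEntry], mods: ModsConfig | None = None):
        self.mods = mods or ModsConfig()
        forms: list[ModifiedPeptide] = []
        for entry in entries:
            forms.extend(enumerate_modified_peptides(entry, self.mods))
        forms.sort(key=lambda f: f.total_mass)
        self.forms = forms
        self.masses = np.array([f.total_mass for f in forms])

    def query_mass(self, mass: float, tol_ppm: float) -> list[ModifiedPeptide]:
        tol = mass * tol_ppm * 1e-6
        lo = int(np.searchsorted(self.masses, mass - tol, side="left"))
        hi = int(np.searchsorted(self.masses, mass + tol, side="right"))
        return self.forms[lo:hi]


def generate_candidates(
    spectrum: Spectrum,
    index: SearchSpaceIndex,
    prec_tol_ppm: float = 10.0,
    charges: Sequence[int] = (2, 3, 4, 5, 6),
) -> list[tuple[ModifiedPeptide, int]]:
    """Modified peptides whose precursor m/z at the spectrum's charge lies
    within ``prec_tol_ppm``. An unknown charge tries every charge in range."""
    trial = (
        [spectrum.precursor_charge]
        if spectrum.precursor_charge is not None
        else list(charges)
    )
    out: list[tuple[ModifiedPeptide, int]] = []
    for z in trial:
        mass = neutral_mass(spectrum.precursor_mz, z)
        for form in index.query_mass(mass, prec_tol_ppm):
            out.append((form, z))
    return out


def score_psm(
    spectrum: Spectrum, candidate: ModifiedPeptide, frag_tol_ppm: float = 20.0
) -> float:
    """Binomial-tail matched-peak score.

    With n theoretical b/y/Y0/Y1 ions (charges 1-2) and k of them matched
    within ``frag_tol_ppm``, the score is -log10 of the binomial survival
    P(X >= k | n, p) where p is the per-ion chance probability estimated from
    peak density: p = clamp(N_peaks * 2*tol_Da(at the median peak m/z) /
    observed m/z span, 1e-6, 0.5). Zero matches (or < 2 peaks) score 0.
    """
    if spectrum.n_peaks < 2:
        return 0.0
    theo = fragment_ions(
        candidate.sequence,
        candidate.placements,
        kinds=("b", "y", "Y0", "Y1"),
        charges=(1, 2),
    )
    targets = [mz for _, mz in theo]
    n = len(targets)
    matches = match_peaks(spectrum, targets, frag_tol_ppm)
    k = len({ti for ti, _ in matches})
    if k == 0:
        return 0.0
    median_mz = float(np.median(spectrum.mz))
    tol_da = median_mz * frag_tol_ppm * 1e-6
    span = float(spectrum.mz[-1] - spectrum.mz[0])
    if span <= 0:
        return 0.0
    p = min(max(spectrum.n_peaks * 2.0 * tol_da / span, 1e-6), 0.5)
    sf = float(binom.sf(k - 1, n, p))
    if sf <= 0:
        sf = 5e-324  # smallest positive float; caps the score deterministically
    return -math.log10(sf)


def search_spectra(
    spectra: Iterable[Spectrum],
    index: SearchSpaceIndex,
    verdicts: Mapping[str, OxoniumVerdict] | None = None,
    prec_tol_ppm: float = 10.0,
    frag_tol_ppm: float = 20.0,
    charges: Sequence[int] = (2, 3, 4, 5, 6),
) -> list[GlycoPSM]:
    """Best PSM per scan under target-decoy competition.

    Target and decoy candidates compete for each spectrum; at equal score the
    decoy wins (conservative tie-break). Spectra with no candidate or a zero
    score yield no PSM.
    """
    verdicts = verdicts or {}
    psms: list[GlycoPSM] = []
    for spectrum in spectra:
        best: GlycoPSM | None = None
        for form, z in generate_candidates(spectrum, index, prec_tol_ppm, charges):
            score = score_psm(spectrum, form, frag_tol_ppm)
            if score <= 0:
                continue
            is_decoy = form.entry.is_decoy
            cand = GlycoPSM(
                scan_id=spectrum.scan_id,
                source_run=spectrum.source_run,
                peptide=form,
                charge=z,
                precursor_mz=spectrum.precursor_mz,
                score=score,
                is_decoy=is_decoy,
                oxonium_passed=(
                    verdicts[spectrum.scan_id].passed
                    if spectrum.scan_id in verdicts
                    else False
                ),
            )
            if (
                best is None
                or cand.score > best.score
                or (cand.score == best.score and cand.is_decoy and not best.is_decoy)
            ):
                best = cand
        if best is not None:
            psms.append(best)
    return assign_fdr(psms)


def assign_fdr(psms: Sequence[GlycoPSM]) -> list[GlycoPSM]:
    """Decoy-based q-values over a one-best-per-scan PSM list.

    At each score threshold t, FDR_est(t) = #decoy(>= t) / max(1, #target(>= t));
    the q-value is the running minimum of FDR_est from the lowest score upward,
    so q is monotone non-increasing in score.
    """
    ranked = sorted(psms, key=lambda p: -p.score)
    n_decoy = 0
    n_target = 0
    fdrs = []
    for psm in ranked:
        if psm.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(1, n_target))
    q = math.inf
    for i in range(len(ranked) - 1, -1, -1):
        q = min(q, fdrs[i])
        ranked[i].q_value = q
    return ranked


def filter_psms(psms: Iterable[GlycoPSM], fdr: float = 0.01) -> list[GlycoPSM]:
    """Target PSMs at q <= ``fdr``.

    An FDR target of 0 is the degenerate no-tolerance boundary and accepts
    nothing: an estimated q of 0 only reflects the absence of higher-scoring
    decoys, not a guarantee of zero false matches.
    """
    if fdr <= 0:
        return []
    return [p for p in psms if not p.is_decoy and p.q_value <= fdr]


@dataclass(frozen=True)
class SpecificitySummary:
    n_site_specific: int
    n_total: int

    @property
    def specificity(self) -> float | None:
        """Percentage of q-passing PSMs that are site-specific O-glycopeptide
        PSMs, to one decimal; None when no PSM passed."""
        if self.n_total == 0:
            return None
        return round(100.0 * self.n_site_specific / self.n_total, 1)


def report_filter(psms: Sequence[GlycoPSM]) -> tuple[list[GlycoPSM], SpecificitySummary]:
    """Keep site-specific O-glycopeptide PSMs (glycan placement, passing
    oxonium verdict, N-terminal S/T) and summarize enrichment specificity."""
    site_specific = [p for p in psms if p.is_site_specific]
    return site_specific, SpecificitySummary(len(site_specific), len(psms))


def localize_sites(
    psms: Iterable[GlycoPSM],
    proteins: Iterable[ProteinRecord] | Mapping[str, str],
) -> list[SiteRecord]:
    """Aggregate site-specific PSMs into protein-anchored glycosylation sites.

    Each PSM contributes a site at the peptide's start position on every
    parent protein (shared peptides are flagged); glycan compositions and
    per-sample PSM counts accumulate per site.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p.sequence for p in proteins}
    records: dict[tuple[str, int], SiteRecord] = {}
    for psm in psms:
        parents = sorted(psm.peptide.entry.parents)
        shared = len({acc for acc, _ in parents}) > 1
        comp = psm.peptide.glycan_composition()
        for acc, start in parents:
            if acc not in proteins:
                continue
            key = (acc, start)
            rec = records.get(key)
            if rec is None:
                rec = SiteRecord(
                    accession=acc,
                    position=start,
                    residue=proteins[acc][start - 1],
                )
                records[key] = rec
            if comp is not None:
                rec.compositions[str(comp)] += 1
            rec.psm_counts[psm.source_run] += 1
            rec.shared = rec.shared or shared
    return sorted(records.values(), key=lambda r: (r.accession, r.position))


def write_psm_table(psms: Sequence[GlycoPSM], path: str | Path, header_comment: str | None = None) -> None:
    """PSM table TSV per the documented column contract."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "scan_id\trun\tpeptide\tmods\tglycan_composition\tcharge\t"
            "precursor_mz\tscore\tq_value\tis_decoy\toxonium_passed\tprotein\tstart\n"
        )
        for p in psms:
            comp = p.peptide.glycan_composition()
            parents = sorted(p.peptide.entry.parents)
            prot = ";".join(acc for acc, _ in parents)
            start = ";".join(str(s) for _, s in parents)
            fh.write(
                f"{p.scan_id}\t{p.source_run}\t{p.peptide.sequence}\t"
                f"{p.peptide.mods_string()}\t{comp if comp else ''}\t{p.charge}\t"
                f"{p.precursor_mz:.5f}\t{p.score:.4f}\t{p.q_value:.6g}\t"
                f"{int(p.is_decoy)}\t{int(p.oxonium_passed)}\t{prot}\t{start}\n"
            )
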