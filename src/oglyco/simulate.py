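"""Synthetic proteomes, planted O-glycosites and annotated HCD spectra.

The generator emulates the study conditions the pipeline targets: random
protein sequences with a realistic Ser/Thr frequency, mucin-type glycosites
planted at S/T with a four-composition glycan mixture anchored at ~69%
core-1 Hex(1)HexNAc(1), a two-condition (tumor/normal) abundance model with
planted fold changes, and centroided HCD-like spectra containing b/y, Y0/Y1
and oxonium ions with ppm-scale mass error and uniform noise peaks.
Everything is seeded and deterministic; every generated glyco spectrum
traces to exactly one planted site-bearing peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import PeptideEntry, ProteinRecord, build_search_space
from .masses import (
    CARBAMIDOMETHYL_C,
    GlycanComposition,
    OxoniumTable,
    fragment_ions,
    peptide_mass,
    precursor_mz,
)
from .spectra import Spectrum

DEFAULT_MIXTURE: tuple[tuple[str, float], ...] = (
    ("Hex(1)HexNAc(1)", 0.69),
    ("HexNAc(1)", 0.16),
    ("Hex(1)HexNAc(2)", 0.08),
    ("Hex(2)HexNAc(2)", 0.07),
)


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic data generator."""

    n_proteins: int = 40
    min_len: int = 80
    max_len: int = 160
    st_frequency: float = 0.12  # combined Ser+Thr residue frequency
    site_probability: float = 0.3  # planting probability per S/T residue
    glycan_mixture: tuple[tuple[str, float], ...] = DEFAULT_MIXTURE
    # two-condition abundance model
    fold_protein_fraction: float = 0.1  # fraction of proteins with a planted fold
    planted_fold: float = 4.0  # up in condition A; matched proteins planted down at 1/fold
    base_psm_rate: float = 3.0  # Poisson rate per site-peptide per sample
    abundance_sigma: float = 0.5  # lognormal spread of per-peptide rates
    # spectrum model
    fragment_coverage: float = 0.85  # fraction of theoretical ions present
    ppm_sigma: float = 2.0  # gaussian m/z error (ppm)
    n_noise_peaks: int = 20
    charge_weights: tuple[tuple[int, float], ...] = ((2, 0.5), (3, 0.35), (4, 0.15))
    n_background_per_run: int = 40  # non-glycosylated peptide spectra per run
    samples: tuple[tuple[str, str], ...] = (("tumor", "A"), ("normal", "B"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_len < 6:
            raise ValueError("max_len must be >= 6")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        w = sum(w for _, w in self.glycan_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("glycan mixture weights must sum to 1")
        for p in (self.st_frequency, self.site_probability, self.fragment_coverage):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth against which pipeline recovery is measured."""

    planted_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    fold_proteins: dict[str, float] = field(default_factory=dict)
    #: per-spectrum provenance rows (filled by :func:`simulate_spectra`)
    spectrum_records: list[dict] = field(default_factory=list)

    @property
    def planted_positions(self) -> set[tuple[str, int]]:
        return {
            (acc, pos) for acc, sites in self.planted_sites.items() for pos, _ in sites
        }

    def observable_sites(self) -> set[tuple[str, int]]:
        """Planted sites for which at least one glyco spectrum was emitted."""
        return {
            (r["accession"], r["site_position"])
            for r in self.spectrum_records
            if r["kind"] == "glyco"
        }


def generate_proteome(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Seeded random proteome with glycosites planted at S/T residues."""
    rng = np.random.default_rng([config.seed, 0])
    non_st = [aa for aa in "ACDEFGHIKLMNPQRVWY"]
    alphabet = non_st + ["S", "T"]
    probs = np.array(
        [(1.0 - config.st_frequency) / len(non_st)] * len(non_st)
        + [config.st_frequency / 2.0] * 2
    )
    probs = probs / probs.sum()
    comps = [c for c, _ in config.glycan_mixture]
    weights = np.array([w for _, w in config.glycan_mixture])

    proteins: list[ProteinRecord] = []
    truth = SyntheticTruth()
    n_fold = round(config.n_proteins * config.fold_protein_fraction)
    fold_idx = set(
        rng.choice(config.n_proteins, size=n_fold, replace=False).tolist()
        if n_fold
        else []
    )
    for i in range(config.n_proteins):
        length = int(rng.integers(config.min_len, config.max_len + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        acc = f"SYN{i:04d}"
        proteins.append(ProteinRecord(accession=acc, sequence=seq))
        sites = []
        for pos0, aa in enumerate(seq):
            if aa in "ST" and rng.random() < config.site_probability:
                comp = comps[int(rng.choice(len(comps), p=weights))]
                sites.append((pos0 + 1, comp))
        truth.planted_sites[acc] = sites
        if i in fold_idx:
            # alternate up/down so condition totals stay roughly balanced
            fold = config.planted_fold if len(truth.fold_proteins) % 2 == 0 else 1.0 / config.planted_fold
            truth.fold_proteins[acc] = fold
    return proteins, truth


@dataclass(frozen=True)
class _SiteAssignment:
    accession: str
    position: int
    composition: str
    entry: PeptideEntry
    rate: float
    fold: float


def _fixed_mods(sequence: str) -> list[tuple[int, object]]:
    return [
        (i, CARBAMIDOMETHYL_C)
        for i, aa in enumerate(sequence, start=1)
        if aa in CARBAMIDOMETHYL_C.targets
    ]


def _assign_site_peptides(
    proteins: Sequence[ProteinRecord],
    truth: SyntheticTruth,
    config: SynthConfig,
    rng: np.random.Generator,
    restrict_accessions: set[str] | None = None,
) -> tuple[list[_SiteAssignment], list[PeptideEntry]]:
    """Pick one search-space peptide per observable planted site and draw its
    abundance rate. Returns the assignments plus the non-glyco background pool."""
    space = build_search_space(proteins)
    by_start: dict[tuple[str, int], list[PeptideEntry]] = {}
    for entry in space:
        if not entry.nterm_st:
            continue
        for acc, start in entry.parents:
            by_start.setdefault((acc, start), []).append(entry)
    assignments = []
    for acc in sorted(truth.planted_sites):
        if restrict_accessions is not None and acc not in restrict_accessions:
            continue
        fold = truth.fold_proteins.get(acc, 1.0)
        for pos, comp in truth.planted_sites[acc]:
            candidates = sorted(by_start.get((acc, pos), []), key=lambda e: e.sequence)
            if not candidates:
                continue  # no 6-46 aa S/T-start peptide exists for this site
            entry = candidates[int(rng.integers(len(candidates)))]
            rate = config.base_psm_rate * float(
                rng.lognormal(0.0, config.abundance_sigma)
            )
            assignments.append(_SiteAssignment(acc, pos, comp, entry, rate, fold))
    background_pool = sorted(
        (
            e
            for e in space
            if not e.nterm_st
            and (
                restrict_accessions is None
                or all(acc in restrict_accessions for acc, _ in e.parents)
            )
        ),
        key=lambda e: e.sequence,
    )
    return assignments, background_pool


def simulate_counts(
    proteins: Sequence[ProteinRecord],
    truth: SyntheticTruth,
    config: SynthConfig,
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, bool]]:
    """True per-peptide PSM counts per sample under the abundance model.

    Returns a counts DataFrame (rows = peptide sequences, columns = samples),
    a map from peptide to parent accessions, and a map marking glyco-site
    rows. A protein's planted fold applies to all of its peptides, glyco or
    not (abundance is a property of the protein); background rows from
    unplanted proteins sit at fold 1 so sample totals reflect the whole run.
    """
    rng = np.random.default_rng([config.seed, 1])
    assignments, background = _assign_site_peptides(proteins, truth, config, rng)
    samples = [name for name, _ in config.samples]
    conditions = {name: cond for name, cond in config.samples}
    rows: dict[str, dict[str, int]] = {}
    parents: dict[str, list[str]] = {}
    is_glyco: dict[str, bool] = {}
    for a in assignments:
        row = rows.setdefault(a.entry.sequence, {s: 0 for s in samples})
        parents.setdefault(
            a.entry.sequence, sorted({acc for acc, _ in a.entry.parents})
        )
        is_glyco[a.entry.sequence] = True
        for s in samples:
            rate = a.rate * (a.fold if conditions[s] == "A" else 1.0)
            row[s] += int(rng.poisson(rate))
    n_bg = min(config.n_background_per_run, len(background))
    if n_bg:
        chosen = rng.choice(len(background), size=n_bg, replace=False)
        for j in sorted(chosen.tolist()):
            entry = background[j]
            accs = sorted({acc for acc, _ in entry.parents})
            fold = truth.fold_proteins.get(accs[0], 1.0)
            rate = config.base_psm_rate * float(
                rng.lognormal(0.0, config.abundance_sigma)
            )
            row = rows.setdefault(entry.sequence, {s: 0 for s in samples})
            parents.setdefault(entry.sequence, accs)
            is_glyco.setdefault(entry.sequence, False)
            for s in samples:
                row[s] += int(rng.poisson(rate * (fold if conditions[s] == "A" else 1.0)))
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=samples)
    counts = counts.fillna(0).astype(int).sort_index()
    return counts, parents, is_glyco


def _make_spectrum(
    scan_id: str,
    run: str,
    sequence: str,
    placements: list,
    charge: int,
    config: SynthConfig,
    rng: np.random.Generator,
    with_oxonium: bool,
    oxonium: OxoniumTable,
) -> Spectrum:
    def jitter(mz: float) -> float:
        if config.ppm_sigma <= 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, config.ppm_sigma) * 1e-6)

    theo = fragment_ions(sequence, placements, kinds=("b", "y", "Y0", "Y1"), charges=(1, 2))
    mzs: list[float] = []
    intens: list[float] = []
    for _, mz in theo:
        if config.fragment_coverage >= 1.0 or rng.random() < config.fragment_coverage:
            mzs.append(jitter(mz))
            intens.append(float(rng.uniform(20.0, 100.0)))
    if with_oxonium:
        for _, mz in oxonium.ions:
            mzs.append(jitter(mz))
            intens.append(float(rng.uniform(50.0, 100.0)))
    for _ in range(config.n_noise_peaks):
        mzs.append(float(rng.uniform(100.0, 2000.0)))
        intens.append(float(rng.uniform(1.0, 10.0)))
    total_mass = peptide_mass(sequence, placements)
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=jitter(precursor_mz(total_mass, charge)),
        precursor_charge=charge,
        mz=np.array(mzs),
        intensity=np.array(intens),
        source_run=run,
    )


def simulate_spectra(
    proteins: Sequence[ProteinRecord],
    truth: SyntheticTruth,
    config: SynthConfig,
    restrict_accessions: set[str] | None = None,
) -> dict[str, list[Spectrum]]:
    """Annotated HCD-like MGF runs, one per sample.

    Glycopeptides are drawn through the digestion rules so planted sites land
    at peptide N-termini; per-condition PSM counts follow the Poisson
    abundance model; each spectrum holds a sampled fraction of theoretical
    b/y + Y0/Y1 ions, the oxonium series, and uniform noise peaks, all
    jittered at the configured ppm error. Background spectra of
    non-glycosylated S/T-containing peptides (no glycan, no oxonium ions) are
    added per run. Provenance rows accumulate in ``truth.spectrum_records``.

    ``restrict_accessions`` limits generating proteins (entrapment designs).
    """
    rng = np.random.default_rng([config.seed, 2])
    assignments, background = _assign_site_peptides(
        proteins, truth, config, rng, restrict_accessions
    )
    oxonium = OxoniumTable()
    charges = [z for z, _ in config.charge_weights]
    charge_p = np.array([w for _, w in config.charge_weights])
    charge_p = charge_p / charge_p.sum()
    conditions = dict(config.samples)
    runs: dict[str, list[Spectrum]] = {name: [] for name, _ in config.samples}
    counter = 0
    for run, cond in config.samples:
        for a in assignments:
            rate = a.rate * (a.fold if cond == "A" else 1.0)
            n_psm = int(rng.poisson(rate))
            for _ in range(n_psm):
                counter += 1
                scan_id = f"{run}:{counter:06d}"
                seq = a.entry.sequence
                placements = _fixed_mods(seq) + [
                    (1, GlycanComposition.parse(a.composition))
                ]
                z = int(rng.choice(charges, p=charge_p))
                spec = _make_spectrum(
                    scan_id, run, seq, placements, z, config, rng, True, oxonium
                )
                runs[run].append(spec)
                truth.spectrum_records.append(
                    {
                        "scan_id": scan_id,
                        "run": run,
                        "condition": cond,
                        "sequence": seq,
                        "glycan": a.composition,
                        "accession": a.accession,
                        "site_position": a.position,
                        "kind": "glyco",
                    }
                )
        n_bg = min(config.n_background_per_run, len(background))
        if n_bg:
            chosen = rng.choice(len(background), size=n_bg, replace=False)
            for j in sorted(chosen.tolist()):
                entry = background[j]
                counter += 1
                scan_id = f"{run}:{counter:06d}"
                seq = entry.sequence
                z = int(rng.choice(charges, p=charge_p))
                spec = _make_spectrum(
                    scan_id, run, seq, _fixed_mods(seq), z, config, rng, False, oxonium
                )
                runs[run].append(spec)
                truth.spectrum_records.append(
                    {
                        "scan_id": scan_id,
                        "run": run,
                        "condition": cond,
                        "sequence": seq,
                        "glycan": "",
                        "accession": "",
                        "site_position": 0,
                        "kind": "background",
                    }
                )
    return runs


def write_truth_tables(truth: SyntheticTruth, out_dir: str | Path) -> None:
    """TSV exports of planted sites, fold proteins and spectrum provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "truth_sites.tsv", "w") as fh:
        fh.write("accession\tposition\tcomposition\n")
        for acc in sorted(truth.planted_sites):
            for pos, comp in truth.planted_sites[acc]:
                fh.write(f"{acc}\t{pos}\t{comp}\n")
    with open(out / "truth_folds.tsv", "w") as fh:
        fh.write("accession\tfold\n")
        for acc, fold in sorted(truth.fold_proteins.items()):
            fh.write(f"{acc}\t{fold}\n")
    if truth.spectrum_records:
        pd.DataFrame(truth.spectrum_records).to_csv(
            out / "truth_spectra.tsv", sep="\t", index=False
        )
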