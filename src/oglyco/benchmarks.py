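"""Recovery and calibration experiments on synthetic ground truth.

Self-contained experiments that exercise the full pipeline against the
synthetic generator's truth: entrapment-style FDR calibration, glycosite
recovery, and spectral-count fold-change recovery. Shared by the property
test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .digestion import ProteinRecord, build_search_space, make_decoys
from .quant import (
    CountMatrix,
    normalize_counts,
    peptide_fold_changes,
    protein_fold_changes,
)
from .search import (
    GlycoPSM,
    ModsConfig,
    SearchSpaceIndex,
    filter_psms,
    localize_sites,
    report_filter,
    search_spectra,
)
from .simulate import (
    SynthConfig,
    SyntheticTruth,
    generate_proteome,
    simulate_counts,
    simulate_spectra,
)
from .spectra import oxonium_filter


def identify(
    proteins: list[ProteinRecord],
    spectra: list,
    fdr: float = 0.01,
    decoy_seed: int = 0,
    mods: ModsConfig | None = None,
) -> tuple[list[GlycoPSM], list[GlycoPSM]]:
    """Digest + search + FDR on in-memory objects.

    Returns ``(accepted, site_specific)``: target PSMs at q <= ``fdr`` and
    their site-specific O-glycopeptide subset.
    """
    decoys = make_decoys(proteins, seed=decoy_seed)
    entries = build_search_space(proteins + decoys)
    index = SearchSpaceIndex(entries, mods)
    verdicts = {s.scan_id: oxonium_filter(s) for s in spectra}
    psms = search_spectra(spectra, index, verdicts)
    accepted = filter_psms(psms, fdr=fdr)
    site_specific, _ = report_filter(accepted)
    return accepted, site_specific


@dataclass(frozen=True)
class EntrapmentResult:
    n_accepted: int
    n_false: int

    @property
    def false_rate(self) -> float:
        return self.n_false / self.n_accepted if self.n_accepted else 0.0


def entrapment_experiment(
    seed: int, n_proteins: int = 16, config: SynthConfig | None = None
) -> EntrapmentResult:
    """FDR calibration by entrapment: spectra from half the proteome,
    searched against the whole proteome plus decoys.

    A false match is an accepted (q <= 0.01) target PSM whose peptide differs
    from the spectrum's generating peptide — matches into the unused half or
    wrong peptides in the used half both count.
    """
    cfg = config or SynthConfig(
        n_proteins=n_proteins, base_psm_rate=2.0, n_background_per_run=30
    )
    cfg = replace(cfg, seed=seed)
    proteins, truth = generate_proteome(cfg)
    half = {p.accession for p in proteins[: len(proteins) // 2]}
    runs = simulate_spectra(proteins, truth, cfg, restrict_accessions=half)
    spectra = [s for specs in runs.values() for s in specs]
    accepted, _ = identify(proteins, spectra)
    true_seq = {r["scan_id"]: r["sequence"] for r in truth.spectrum_records}
    n_false = sum(1 for p in accepted if p.peptide.sequence != true_seq[p.scan_id])
    return EntrapmentResult(n_accepted=len(accepted), n_false=n_false)


@dataclass(frozen=True)
class RecoveryResult:
    n_observable: int
    n_recovered: int
    n_false_sites: int
    specificity: float | None

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_observable if self.n_observable else 0.0


def site_recovery_experiment(
    seed: int, noiseless: bool = False, n_proteins: int = 20
) -> RecoveryResult:
    """Run the pipeline end to end and compare recovered site positions with
    the planted truth.

    Observable sites are planted sites for which at least one spectrum was
    generated (a Poisson count can be zero, and a site without any 6-46 aa
    S/T-start peptide cannot be observed by construction). ``noiseless``
    switches to perfect spectra: full fragment coverage, no m/z error, no
    noise peaks.
    """
    cfg = SynthConfig(n_proteins=n_proteins, seed=seed)
    if noiseless:
        cfg = replace(cfg, fragment_coverage=1.0, ppm_sigma=0.0, n_noise_peaks=0)
    proteins, truth = generate_proteome(cfg)
    runs = simulate_spectra(proteins, truth, cfg)
    spectra = [s for specs in runs.values() for s in specs]
    accepted, site_specific = identify(proteins, spectra)
    _, summary = report_filter(accepted)
    sites = localize_sites(site_specific, proteins)
    recovered = {(s.accession, s.position) for s in sites}
    observable = truth.observable_sites()
    return RecoveryResult(
        n_observable=len(observable),
        n_recovered=len(recovered & observable),
        n_false_sites=len(recovered - truth.planted_positions),
        specificity=summary.specificity,
    )


@dataclass(frozen=True)
class QuantRecoveryResult:
    #: estimated fold per qualifying planted-up protein (>= min_psm in each condition)
    up_estimates: tuple[float, ...]
    down_estimates: tuple[float, ...]
    n_up_significant: int
    n_down_significant: int
    n_null: int
    n_null_significant: int


def quant_recovery_experiment(
    seed: int,
    config: SynthConfig | None = None,
    min_psm_per_condition: int = 20,
) -> QuantRecoveryResult:
    """Spectral-count fold-change recovery on true PSM counts.

    Generates a proteome with planted protein folds (up at ``planted_fold``,
    matched proteins down at its reciprocal), draws per-peptide Poisson
    counts, runs the quant stage, and compares protein-level estimates with
    the truth. Proteins qualify for fold comparison when their raw glyco PSM
    count reaches ``min_psm_per_condition`` in both conditions.
    """
    cfg = config or SynthConfig(
        n_proteins=40,
        base_psm_rate=8.0,
        fold_protein_fraction=0.1,
        n_background_per_run=40,
    )
    cfg = replace(cfg, seed=seed)
    proteins, truth = generate_proteome(cfg)
    counts, parents, is_glyco = simulate_counts(proteins, truth, cfg)
    samples = [name for name, _ in cfg.samples]
    cond_a = [s for s, c in cfg.samples if c == "A"]
    cond_b = [s for s, c in cfg.samples if c == "B"]
    glyco_rows = [p for p in counts.index if is_glyco.get(p)]
    matrix = CountMatrix(counts=counts.loc[glyco_rows], totals=counts.sum(axis=0))
    normalized = normalize_counts(matrix)
    records = peptide_fold_changes(normalized, cond_a, cond_b)
    results = protein_fold_changes(records, parents, matrix.counts, cond_a, cond_b)

    raw_a = {
        acc: int(
            counts.loc[[p for p in glyco_rows if acc in parents[p]], cond_a].values.sum()
        )
        for acc in {a for p in glyco_rows for a in parents[p]}
    }
    raw_b = {
        acc: int(
            counts.loc[[p for p in glyco_rows if acc in parents[p]], cond_b].values.sum()
        )
        for acc in raw_a
    }

    up_est, down_est = [], []
    n_up_sig = n_down_sig = n_null = n_null_sig = 0
    for res in results:
        fold_truth = truth.fold_proteins.get(res.accession, 1.0)
        qualifies = (
            raw_a.get(res.accession, 0) >= min_psm_per_condition
            and raw_b.get(res.accession, 0) >= min_psm_per_condition
        )
        if fold_truth > 1.0:
            if qualifies:
                up_est.append(res.fold_change)
                n_up_sig += int(res.significant)
        elif fold_truth < 1.0:
            if qualifies:
                down_est.append(res.fold_change)
                n_down_sig += int(res.significant)
        else:
            n_null += 1
            n_null_sig += int(res.significant)
    return QuantRecoveryResult(
        up_estimates=tuple(up_est),
        down_estimates=tuple(down_est),
        n_up_significant=n_up_sig,
        n_down_significant=n_down_sig,
        n_null=n_null,
        n_null_significant=n_null_sig,
    )
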