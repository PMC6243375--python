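"""End-to-end orchestration: digest -> spectra -> search -> quant -> sites.

``run_pipeline`` executes the stages against a :class:`~oglyco.config.RunConfig`
and writes the output tables (PSMs, sites, peptide- and protein-level
quantification, motif/enrichment/landscape summaries) plus a run manifest.
Idempotent for a fixed seed and inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .digestion import build_search_space, make_decoys, read_fasta, write_fasta
from .quant import (
    CountMatrix,
    normalize_counts,
    peptide_fold_changes,
    protein_fold_changes,
    write_peptide_table,
    write_protein_table,
)
from .search import (
    SearchSpaceIndex,
    filter_psms,
    localize_sites,
    report_filter,
    search_spectra,
    write_psm_table,
)
from .sites import (
    center_composition,
    motif_windows,
    relative_positions,
    residue_enrichment,
    sites_per_protein,
    write_site_table,
    write_windows_fasta,
)
from .spectra import oxonium_filter, read_spectra, write_verdicts

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    out_dir: Path
    psms: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    site_specific: list = field(default_factory=list)
    specificity: float | None = None
    sites: list = field(default_factory=list)
    protein_quant: list = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"oglyco {__version__} config={config.config_hash()}"
    result = PipelineResult(out_dir=out)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("digest")
        targets = read_fasta(config.fasta)
        decoys = make_decoys(
            targets, seed=config.decoy_seed, preserve_kr=config.decoy_preserve_kr
        )
        write_fasta(decoys, out / "decoys.fasta")
        entries = build_search_space(
            targets + decoys,
            tryp_mc=config.tryp_mc,
            oper_mc=config.oper_mc,
            min_len=config.min_len,
            max_len=config.max_len,
            proline_rule=config.proline_rule,
        )
    except Exception as exc:
        raise RuntimeError(f"stage digest failed: {exc}") from exc

    try:
        stage("spectra")
        spectra = []
        for path in config.spectra:
            spectra.extend(read_spectra(path))
        table = config.oxonium()
        verdicts = {
            s.scan_id: oxonium_filter(
                s,
                table,
                tol_ppm=config.oxonium_tol_ppm,
                min_rel_intensity=config.oxonium_min_rel_intensity,
            )
            for s in spectra
        }
        write_verdicts(verdicts.values(), out / "oxonium_verdicts.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage spectra failed: {exc}") from exc

    try:
        stage("search")
        index = SearchSpaceIndex(entries, config.mods_config())
        psms = search_spectra(
            spectra,
            index,
            verdicts,
            prec_tol_ppm=config.precursor_tol_ppm,
            frag_tol_ppm=config.fragment_tol_ppm,
            charges=tuple(config.charges),
        )
        write_psm_table(psms, out / "psms.tsv", header_comment=stamp)
        accepted = filter_psms(psms, fdr=config.fdr)
        site_specific, summary = report_filter(accepted)
        result.psms = psms
        result.accepted = accepted
        result.site_specific = site_specific
        result.specificity = summary.specificity
        result.sites = localize_sites(site_specific, targets)
        write_site_table(result.sites, out / "sites.tsv")
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage search failed: {exc}") from exc

    try:
        stage("quant")
        samples = sorted({s.source_run for s in spectra})
        cond_a = [r for r, c in config.sample_map.items() if c == "A" and r in samples]
        cond_b = [r for r, c in config.sample_map.items() if c == "B" and r in samples]
        if cond_a and cond_b and accepted:
            matrix = CountMatrix.from_psms(site_specific, all_psms=accepted)
            normalized = normalize_counts(matrix)
            records = peptide_fold_changes(normalized, cond_a, cond_b)
            parent_map = {}
            for p in site_specific:
                parent_map.setdefault(
                    p.peptide.sequence,
                    sorted({acc for acc, _ in p.peptide.entry.parents}),
                )
            proteins_q = protein_fold_changes(
                records, parent_map, matrix.counts, cond_a, cond_b
            )
            result.protein_quant = proteins_q
            write_peptide_table(records, matrix.counts, out / "peptide_quant.tsv")
            write_protein_table(proteins_q, out / "protein_quant.tsv")
            matrix.counts.to_csv(out / "count_matrix.tsv", sep="\t")
        else:
            # boundary: nothing accepted or no two-condition design -> empty tables
            for name in ("peptide_quant.tsv", "protein_quant.tsv", "count_matrix.tsv"):
                (out / name).write_text("# empty: no accepted PSMs or no A/B design\n")
    except Exception as exc:
        raise RuntimeError(f"stage quant failed: {exc}") from exc

    try:
        stage("sites")
        if result.sites:
            windows, excluded = motif_windows(result.sites, targets)
            write_windows_fasta(windows, out / "motif_windows.fasta")
            if windows:
                residue_enrichment(windows).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False
                )
                centers = center_composition(windows)
            else:
                centers = {}
            rel = relative_positions(result.sites, targets)
            pd.DataFrame(
                [
                    {"accession": s.accession, "position": s.position, "relative_pct": pct}
                    for s, pct in rel
                ]
            ).to_csv(out / "relative_positions.tsv", sep="\t", index=False)
            sites_per_protein(result.sites).to_csv(
                out / "sites_per_protein.tsv", sep="\t", index=False
            )
        else:
            windows, excluded, centers = [], 0, {}
            for name in (
                "motif_windows.fasta",
                "enrichment.tsv",
                "relative_positions.tsv",
                "sites_per_protein.tsv",
            ):
                (out / name).write_text("")
    except Exception as exc:
        raise RuntimeError(f"stage sites failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_spectra": len(spectra),
        "n_search_space": len(entries),
        "n_psms": len(psms),
        "n_accepted": len(accepted),
        "n_site_specific": len(site_specific),
        "specificity_pct": result.specificity,
        "n_sites": len(result.sites),
        "n_motif_windows": len(windows),
        "n_windows_excluded": excluded,
        "center_composition": {k: round(v, 4) for k, v in centers.items()},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return result
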