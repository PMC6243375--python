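"""Site-centric characterization of the mapped O-glycoproteome.

15-mer motif windows centered on the glycosylation site, position-wise
residue enrichment against a background, Ser/Thr center composition, the
relative-position landscape along proteins, and per-protein site counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .digestion import ProteinRecord

WINDOW_FLANK = 7  # residues on each side; windows are 15-mers
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SiteRecord:
    """A protein-anchored O-glycosylation site.

    ``compositions`` is a histogram of glycan composition strings observed at
    the site; ``psm_counts`` counts supporting PSMs per sample. ``shared``
    marks sites whose supporting peptides map to more than one protein.
    """

    accession: str
    position: int  # 1-based residue index
    residue: str
    compositions: Counter = field(default_factory=Counter)
    psm_counts: Counter = field(default_factory=Counter)
    shared: bool = False

    @property
    def total_psms(self) -> int:
        return sum(self.psm_counts.values())


@dataclass(frozen=True)
class MotifWindow:
    accession: str
    position: int
    window: str  # 15 residues, site at center (index 7)

    def __post_init__(self) -> None:
        if len(self.window) != 2 * WINDOW_FLANK + 1:
            raise ValueError(f"window must be {2 * WINDOW_FLANK + 1} residues")

    @property
    def center(self) -> str:
        return self.window[WINDOW_FLANK]


def _protein_map(proteins: Iterable[ProteinRecord]) -> dict[str, str]:
    return {p.accession: p.sequence for p in proteins}


def motif_windows(
    sites: Iterable[SiteRecord],
    proteins: Iterable[ProteinRecord] | Mapping[str, str],
    include_tyrosine: bool = False,
) -> tuple[list[MotifWindow], int]:
    """Extract the 15-residue window around each site (site at center).

    Sites within 7 residues of either protein terminus lack a full window and
    are excluded (counted, not padded). Tyr-centered sites are excluded from
    the S/T logo by default. Returns ``(windows, n_excluded)``.
    """
    seqs = proteins if isinstance(proteins, Mapping) else _protein_map(proteins)
    windows: list[MotifWindow] = []
    excluded = 0
    for site in sites:
        seq = seqs[site.accession]
        if site.position > len(seq):
            raise ValueError(
                f"site {site.accession}:{site.position} beyond protein length {len(seq)}"
            )
        if not include_tyrosine and site.residue not in "ST":
            excluded += 1
            continue
        if site.position - WINDOW_FLANK < 1 or site.position + WINDOW_FLANK > len(seq):
            excluded += 1
            continue
        win = seq[site.position - WINDOW_FLANK - 1 : site.position + WINDOW_FLANK]
        windows.append(MotifWindow(site.accession, site.position, win))
    return windows, excluded


def background_frequencies(windows: Sequence[MotifWindow]) -> dict[str, float]:
    """Residue frequencies over all window positions excluding the center."""
    counts: Counter = Counter()
    for w in windows:
        counts.update(w.window[:WINDOW_FLANK])
        counts.update(w.window[WINDOW_FLANK + 1 :])
    total = sum(counts.values())
    return {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}


def residue_enrichment(
    windows: Sequence[MotifWindow],
    background: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-offset, per-residue enrichment around the glycosite.

    For each residue r at offset d != 0: a two-sided binomial test of the
    observed count among N windows against the background frequency, and
    log2 odds of observed vs background frequency. Bonferroni adjustment is
    applied across the 20 x 14 grid. The center is characterized separately
    (see :func:`center_composition`).
    """
    if not windows:
        raise ValueError("no motif windows supplied")
    bg = dict(background) if background is not None else background_frequencies(windows)
    n = len(windows)
    rows = []
    offsets = [d for d in range(-WINDOW_FLANK, WINDOW_FLANK + 1) if d != 0]
    n_tests = len(offsets) * len(AMINO_ACIDS)
    for d in offsets:
        col = [w.window[WINDOW_FLANK + d] for w in windows]
        counts = Counter(col)
        for aa in AMINO_ACIDS:
            k = counts.get(aa, 0)
            p_bg = bg.get(aa, 0.0)
            if p_bg <= 0:
                p_val = 1.0 if k == 0 else 0.0
                log_odds = np.nan
            else:
                p_val = binomtest(k, n, p_bg, alternative="two-sided").pvalue
                freq = k / n
                log_odds = np.log2(freq / p_bg) if freq > 0 else -np.inf
            rows.append(
                {
                    "offset": d,
                    "residue": aa,
                    "observed": k,
                    "expected": n * p_bg,
                    "log_odds": log_odds,
                    "p_value": p_val,
                    "p_adjusted": min(1.0, p_val * n_tests),
                }
            )
    return pd.DataFrame(rows)


def center_composition(windows: Sequence[MotifWindow]) -> dict[str, float]:
    """Fraction of windows centered on each residue (the Ser/Thr split)."""
    if not windows:
        raise ValueError("no motif windows supplied")
    counts = Counter(w.center for w in windows)
    n = len(windows)
    return {aa: counts[aa] / n for aa in sorted(counts)}


def relative_positions(
    sites: Iterable[SiteRecord],
    proteins: Iterable[ProteinRecord] | Mapping[str, str],
) -> list[tuple[SiteRecord, float]]:
    """Relative site position: 100 * position / protein length, in (0, 100]."""
    seqs = proteins if isinstance(proteins, Mapping) else _protein_map(proteins)
    out = []
    for site in sites:
        length = len(seqs[site.accession])
        if length == 0:
            raise ValueError(f"protein {site.accession} has length 0")
        out.append((site, 100.0 * site.position / length))
    return out


def sites_per_protein(sites: Iterable[SiteRecord]) -> pd.DataFrame:
    """Distinct-site counts per protein, descending."""
    distinct = {(s.accession, s.position) for s in sites}
    counts = Counter(acc for acc, _ in distinct)
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["accession", "n_sites"],
    )
    return df


def compare_reference(
    sites: Iterable[SiteRecord], reference: set[tuple[str, int]] | str | Path
) -> pd.DataFrame:
    """Mark each site known/novel against a user-supplied reference.

    ``reference`` is a set of (accession, position) pairs or a TSV path with
    columns ``accession`` and ``position``.
    """
    if not isinstance(reference, set):
        ref_df = pd.read_csv(reference, sep="\t")
        reference = set(zip(ref_df["accession"], ref_df["position"].astype(int)))
    rows = [
        {
            "accession": s.accession,
            "position": s.position,
            "residue": s.residue,
            "known": (s.accession, s.position) in reference,
        }
        for s in sites
    ]
    return pd.DataFrame(rows)


def write_site_table(
    sites: Sequence[SiteRecord], path: str | Path, samples: Sequence[str] | None = None
) -> None:
    """Site table TSV: accession, position, residue, composition histogram,
    per-sample PSM counts."""
    if samples is None:
        labels: set[str] = set()
        for s in sites:
            labels.update(s.psm_counts)
        samples = sorted(labels)
    with open(path, "w") as fh:
        cols = ["accession", "position", "residue", "compositions", "shared"]
        cols += [f"psm_{s}" for s in samples]
        fh.write("\t".join(cols) + "\n")
        for s in sorted(sites, key=lambda s: (s.accession, s.position)):
            comp = ";".join(f"{c}:{n}" for c, n in sorted(s.compositions.items()))
            row = [s.accession, str(s.position), s.residue, comp, str(int(s.shared))]
            row += [str(s.psm_counts.get(lbl, 0)) for lbl in samples]
            fh.write("\t".join(row) + "\n")


def write_windows_fasta(windows: Sequence[MotifWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.accession}:{w.position}\n{w.window}\n")
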