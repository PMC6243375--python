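"""Sequential in-silico trypsin + O-glycoprotease digestion.

The search space is built in two stages: trypsin cleaves C-terminal to
Lys/Arg with a missed-cleavage budget, then the O-glycan-dependent
endoprotease (OpeRATOR) cleaves N-terminal to Ser/Thr with its own budget,
so that released glycopeptides start at the glycosylation site. Products are
then filtered to Ser/Thr-containing peptides of 6-46 residues and
deduplicated by sequence.

Missed-cleavage accounting: for trypsin, internal K/R residues (any position
except the last) count; for the O-glycoprotease, internal S/T residues
(positions 2..n) count — the N-terminal S/T of a fragment is the used cut
site, not a missed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import fasta as _fasta

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")


@dataclass
class PeptideEntry:
    """One non-redundant search-space peptide with provenance.

    ``parents`` maps every (protein accession, 1-based start) the sequence
    occurs at under the digestion rules. ``tryptic_mc`` is the smallest
    missed-cleavage count of any tryptic parent; ``operator_mc`` is the
    number of internal S/T (positions 2..n), intrinsic to the sequence.
    """

    sequence: str
    parents: set[tuple[str, int]] = field(default_factory=set)
    tryptic_mc: int = 0
    operator_mc: int = 0

    @property
    def nterm_st(self) -> bool:
        return self.sequence[0] in "ST"

    @property
    def is_decoy(self) -> bool:
        return all(acc.startswith(DECOY_PREFIX) for acc, _ in self.parents)


def internal_st_count(sequence: str) -> int:
    """Number of S/T residues at positions 2..n of ``sequence``."""
    return sum(1 for aa in sequence[1:] if aa in "ST")


def tryptic_digest(
    sequence: str, max_missed: int, proline_rule: bool = False
) -> list[tuple[str, int, int]]:
    """Tryptic peptides of ``sequence`` as ``(peptide, start, missed)``.

    Cleavage is C-terminal to K/R; ``proline_rule`` suppresses cleavage
    before proline. ``start`` is 1-based. Every product with at most
    ``max_missed`` internal K/R cleavage sites is returned.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    n = len(sequence)
    # cut points: indices where a peptide may start/end (0-based boundaries)
    cuts = [0]
    for i in range(n - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(n)
    out = []
    for ci in range(len(cuts) - 1):
        for cj in range(ci + 1, len(cuts)):
            missed = cj - ci - 1
            if missed > max_missed:
                break
            out.append((sequence[cuts[ci] : cuts[cj]], cuts[ci] + 1, missed))
    return out


def operator_digest(peptide: str, max_missed: int) -> list[tuple[str, int, int]]:
    """O-glycoprotease fragments of ``peptide`` as ``(fragment, offset, missed)``.

    Cut sites sit immediately before each S/T at positions >= 2; products are
    all sub-fragments between chosen boundaries whose retained internal S/T
    count is at most ``max_missed``. ``offset`` is the 1-based start within
    ``peptide``. The uncleaved input is included when its internal S/T count
    fits the budget.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    n = len(peptide)
    sites = [i for i in range(1, n) if peptide[i] in "ST"]  # 0-based cut positions
    bounds = [0] + sites + [n]
    out = []
    for bi in range(len(bounds) - 1):
        for bj in range(bi + 1, len(bounds)):
            missed = bj - bi - 1
            if missed > max_missed:
                break
            out.append((peptide[bounds[bi] : bounds[bj]], bounds[bi] + 1, missed))
    return out


def build_search_space(
    proteins: Iterable[ProteinRecord],
    tryp_mc: int = 2,
    oper_mc: int = 5,
    min_len: int = 6,
    max_len: int = 46,
    proline_rule: bool = False,
) -> list[PeptideEntry]:
    """Non-redundant S/T-containing peptides from sequential dual digestion.

    Each protein is digested by trypsin (<= ``tryp_mc`` missed cleavages),
    every product is re-digested by the O-glycoprotease (<= ``oper_mc``),
    and fragments are kept when they contain at least one S/T and have
    ``min_len``-``max_len`` residues. Identical sequences are merged; their
    ``parents`` aggregate every origin.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("protein collection is empty")
    entries: dict[str, PeptideEntry] = {}
    for prot in proteins:
        for pep, pstart, pmissed in tryptic_digest(prot.sequence, tryp_mc, proline_rule):
            for frag, offset, fmissed in operator_digest(pep, oper_mc):
                if not (min_len <= len(frag) <= max_len):
                    continue
                if not any(aa in "ST" for aa in frag):
                    continue
                start = pstart + offset - 1
                entry = entries.get(frag)
                if entry is None:
                    entry = PeptideEntry(
                        sequence=frag,
                        tryptic_mc=pmissed,
                        operator_mc=internal_st_count(frag),
                    )
                    entries[frag] = entry
                entry.parents.add((prot.accession, start))
                entry.tryptic_mc = min(entry.tryptic_mc, pmissed)
    return list(entries.values())


def make_decoys(
    proteins: Iterable[ProteinRecord], seed: int, preserve_kr: bool = False
) -> list[ProteinRecord]:
    """Protein-level randomized decoys: one shuffled twin per target.

    Residues are permuted with a generator seeded by ``seed`` (deterministic),
    keeping length and residue multiset. With ``preserve_kr`` the K/R
    positions are fixed and only the remaining residues are permuted, so the
    decoy tryptic length distribution matches the target's.
    """
    rng = np.random.default_rng(seed)
    out = []
    for prot in proteins:
        residues = list(prot.sequence)
        if preserve_kr:
            idx = [i for i, aa in enumerate(residues) if aa not in "KR"]
            sub = [residues[i] for i in idx]
            rng.shuffle(sub)
            for i, aa in zip(idx, sub):
                residues[i] = aa
        else:
            rng.shuffle(residues)
        out.append(
            ProteinRecord(
                accession=DECOY_PREFIX + prot.accession,
                sequence="".join(residues),
                is_decoy=True,
            )
        )
    return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA; the accession is the first whitespace-delimited
    header token, and a ``DECOY_`` prefix marks decoys."""
    out = []
    seen = set()
    with _fasta.read(str(path)) as reader:
        for header, seq in reader:
            accession = header.split()[0]
            if accession in seen:
                raise ValueError(f"duplicate accession {accession!r} in {path}")
            seen.add(accession)
            out.append(
                ProteinRecord(
                    accession=accession,
                    sequence=seq.upper(),
                    is_decoy=accession.startswith(DECOY_PREFIX),
                )
            )
    return out


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.accession}\n")
            seq = prot.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_search_space(entries: Sequence[PeptideEntry], path: str | Path) -> None:
    """TSV export: sequence, parents (acc:start;...), tryptic_mc, operator_mc, nterm_st."""
    with open(path, "w") as fh:
        fh.write("sequence\tparents\ttryptic_mc\toperator_mc\tnterm_st\n")
        for e in sorted(entries, key=lambda e: e.sequence):
            parents = ";".join(f"{acc}:{start}" for acc, start in sorted(e.parents))
            fh.write(f"{e.sequence}\t{parents}\t{e.tryptic_mc}\t{e.operator_mc}\t{int(e.nterm_st)}\n")
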