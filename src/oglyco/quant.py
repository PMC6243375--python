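"""Spectral-counting label-free quantification between two conditions.

PSM counts per peptide are normalized by each sample's total PSM count,
peptide fold changes are A/B ratios of summed normalized counts (with
pseudo-folds 2.0 / 0.5 for condition-exclusive peptides so a protein-level
fold can still be formed), protein folds are plain arithmetic means of their
peptide folds, and significance requires at least a twofold change together
with a raw PSM difference of at least 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .search import GlycoPSM

PSEUDO_FOLD_A_ONLY = 2.0
PSEUDO_FOLD_B_ONLY = 0.5


@dataclass
class CountMatrix:
    """PSM counts (rows = peptide or site identifiers, columns = samples).

    ``totals`` are per-sample totals over ALL q-passing PSMs — not only the
    glyco-filtered rows — matching total-PSM normalization.
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("PSM counts must be non-negative")
        missing = set(self.counts.columns) - set(self.totals.index)
        if missing:
            raise ValueError(f"totals missing for samples: {sorted(missing)}")

    @classmethod
    def from_psms(
        cls,
        quant_psms: Sequence[GlycoPSM],
        all_psms: Sequence[GlycoPSM] | None = None,
        key: str = "peptide",
    ) -> "CountMatrix":
        """Count PSMs per identifier per sample.

        ``key`` is ``"peptide"`` (aggregates glycoforms and charge states of
        one sequence) or ``"glycoform"`` (sequence + composition). Totals are
        computed from ``all_psms`` (default: ``quant_psms``).
        """
        if all_psms is None:
            all_psms = quant_psms
        rows: dict[str, dict[str, int]] = {}
        samples = sorted({p.source_run for p in all_psms})
        for p in quant_psms:
            if key == "peptide":
                ident = p.peptide.sequence
            elif key == "glycoform":
                comp = p.peptide.glycan_composition()
                ident = f"{p.peptide.sequence}|{comp if comp else ''}"
            else:
                raise ValueError(f"unknown key {key!r}")
            rows.setdefault(ident, {})
            rows[ident][p.source_run] = rows[ident].get(p.source_run, 0) + 1
        counts = pd.DataFrame.from_dict(rows, orient="index").reindex(
            columns=samples, fill_value=0
        )
        counts = counts.fillna(0).astype(int).sort_index()
        totals = pd.Series(
            {s: sum(1 for p in all_psms if p.source_run == s) for s in samples}
        )
        return cls(counts=counts, totals=totals)


@dataclass(frozen=True)
class FoldChangeRecord:
    identifier: str
    norm_a: float
    norm_b: float
    fold_change: float
    pseudo: bool


@dataclass(frozen=True)
class ProteinQuantResult:
    accession: str
    fold_change: float
    psm_a: int
    psm_b: int
    n_peptides: int
    shared_peptides: bool = False

    @property
    def psm_difference(self) -> int:
        return abs(self.psm_a - self.psm_b)

    @property
    def significant(self) -> bool:
        return (
            (self.fold_change >= 2.0 or self.fold_change <= 0.5)
            and self.psm_difference >= 10
        )


def normalize_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Divide each count by its sample's total PSM count."""
    for sample in matrix.counts.columns:
        if matrix.totals[sample] <= 0:
            raise ValueError(f"sample {sample!r} has a zero PSM total")
    return matrix.counts / matrix.totals[matrix.counts.columns]


def peptide_fold_changes(
    normalized: pd.DataFrame,
    cond_a: Sequence[str],
    cond_b: Sequence[str],
) -> list[FoldChangeRecord]:
    """Fold change per row: summed normalized counts in condition A over B.

    Rows exclusive to A get the pseudo-fold 2.0, exclusive to B get 0.5, and
    rows absent from both conditions are excluded.
    """
    cond_a, cond_b = list(cond_a), list(cond_b)
    if not cond_a or not cond_b:
        raise ValueError("both condition groups must be non-empty")
    if set(cond_a) & set(cond_b):
        raise ValueError("condition groups must be disjoint")
    out = []
    for ident, row in normalized.iterrows():
        a = float(row[cond_a].sum())
        b = float(row[cond_b].sum())
        if a == 0 and b == 0:
            continue
        if b == 0:
            fold, pseudo = PSEUDO_FOLD_A_ONLY, True
        elif a == 0:
            fold, pseudo = PSEUDO_FOLD_B_ONLY, True
        else:
            fold, pseudo = a / b, False
        out.append(FoldChangeRecord(str(ident), a, b, fold, pseudo))
    return out


def protein_fold_changes(
    records: Sequence[FoldChangeRecord],
    peptide_proteins: Mapping[str, Sequence[str]],
    raw_counts: pd.DataFrame,
    cond_a: Sequence[str],
    cond_b: Sequence[str],
) -> list[ProteinQuantResult]:
    """Protein fold = arithmetic mean of its peptide folds (pseudo included).

    ``peptide_proteins`` maps each identifier to its parent accessions;
    shared peptides count toward every parent (flagged). The PSM difference
    uses raw counts summed per condition.
    """
    by_protein: dict[str, list[FoldChangeRecord]] = {}
    shared_flag: dict[str, bool] = {}
    for rec in records:
        parents = list(peptide_proteins.get(rec.identifier, ()))
        for acc in parents:
            by_protein.setdefault(acc, []).append(rec)
            if len(parents) > 1:
                shared_flag[acc] = True
    out = []
    for acc, recs in sorted(by_protein.items()):
        fold = sum(r.fold_change for r in recs) / len(recs)
        idents = [r.identifier for r in recs]
        sub = raw_counts.loc[[i for i in idents if i in raw_counts.index]]
        psm_a = int(sub[list(cond_a)].values.sum())
        psm_b = int(sub[list(cond_b)].values.sum())
        out.append(
            ProteinQuantResult(
                accession=acc,
                fold_change=fold,
                psm_a=psm_a,
                psm_b=psm_b,
                n_peptides=len(recs),
                shared_peptides=shared_flag.get(acc, False),
            )
        )
    return out


def write_peptide_table(
    records: Sequence[FoldChangeRecord], raw_counts: pd.DataFrame, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("identifier\t" + "\t".join(map(str, raw_counts.columns)))
        fh.write("\tnorm_a\tnorm_b\tfold_change\tpseudo\n")
        for r in records:
            row = raw_counts.loc[r.identifier] if r.identifier in raw_counts.index else None
            counts = (
                "\t".join(str(int(v)) for v in row.values)
                if row is not None
                else "\t".join("0" for _ in raw_counts.columns)
            )
            fh.write(
                f"{r.identifier}\t{counts}\t{r.norm_a:.6g}\t{r.norm_b:.6g}\t"
                f"{r.fold_change:.4g}\t{int(r.pseudo)}\n"
            )


def write_protein_table(results: Sequence[ProteinQuantResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "accession\tfold_change\tpsm_a\tpsm_b\tpsm_difference\t"
            "n_peptides\tshared_peptides\tsignificant\n"
        )
        for r in results:
            fh.write(
                f"{r.accession}\t{r.fold_change:.4g}\t{r.psm_a}\t{r.psm_b}\t"
                f"{r.psm_difference}\t{r.n_peptides}\t{int(r.shared_peptides)}\t"
                f"{int(r.significant)}\n"
            )
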