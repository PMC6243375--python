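"""Spectral-counting quantification between tumor and normal conditions.

Draws true per-peptide PSM counts from the generator's abundance model
(some proteins planted at fold 4 up or down), normalizes by sample totals,
and reports protein-level fold changes with the significance rule:
at least twofold change AND at least a 10-PSM difference.
"""

from oglyco import (
    CountMatrix,
    SynthConfig,
    generate_proteome,
    normalize_counts,
    peptide_fold_changes,
    protein_fold_changes,
    simulate_counts,
)

cfg = SynthConfig(n_proteins=30, base_psm_rate=8.0, fold_protein_fraction=0.2, seed=11)
proteins, truth = generate_proteome(cfg)
counts, parents, is_glyco = simulate_counts(proteins, truth, cfg)

glyco_rows = [p for p in counts.index if is_glyco.get(p)]
matrix = CountMatrix(counts=counts.loc[glyco_rows], totals=counts.sum(axis=0))
records = peptide_fold_changes(normalize_counts(matrix), ["tumor"], ["normal"])
results = protein_fold_changes(records, parents, matrix.counts, ["tumor"], ["normal"])

n_pseudo = sum(r.pseudo for r in records)
print(f"quantified peptides: {len(records)} ({n_pseudo} condition-exclusive, pseudo-fold)")
print(f"quantified proteins: {len(results)}\n")
print("significant proteins (|fold| >= 2 and PSM difference >= 10):")
for r in sorted(results, key=lambda r: -abs(r.psm_difference)):
    if r.significant:
        truth_fold = truth.fold_proteins.get(r.accession, 1.0)
        print(
            f"  {r.accession}  fold={r.fold_change:5.2f}  "
            f"PSMs tumor/normal={r.psm_a}/{r.psm_b}  (planted fold {truth_fold})"
        )
print(
    "\nEstimated folds track the planted values; condition-exclusive peptides\n"
    "enter the protein mean at the pseudo-folds 2.0 (tumor-only) or 0.5\n"
    "(normal-only)."
)
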