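# Methods

## The enrichment model

The pipeline models data from an enzyme-assisted enrichment in which an
O-glycan-dependent endoprotease cleaves the peptide backbone on the
N-terminal side of a glycan-occupied Ser or Thr. Proteins are first
digested with trypsin, peptides are conjugated to a solid support, and the
protease releases only glycopeptides — each beginning at its glycosylation
site and still carrying the glycan. Computationally this has three
consequences the package exploits throughout:

- the search space is the *composition* of two digestions with independent
  missed-cleavage budgets (trypsin ≤ 2, O-glycoprotease ≤ 5), filtered to
  S/T-containing peptides of 6–46 residues;
- a confident glycopeptide identification localizes its site for free: the
  site is the peptide's start position on the parent protein;
- glycopeptide spectra carry diagnostic glycan oxonium ions, usable as a
  presence-only prefilter.

Peptides that contain S/T but do not start with one (tryptic N-terminus
with downstream missed protease sites) are deliberately retained: they are
the denominator of the enrichment specificity, `100·a/(a+b)` where `a`
counts site-specific PSMs (N-terminal S/T, glycan placed, oxonium-positive)
among `a+b` accepted PSMs.

## Digestion semantics

Trypsin cuts C-terminal to K/R with no proline exception by default (a
config flag enables K/R-not-before-P). The O-glycoprotease cuts
immediately before each S/T at positions ≥ 2 of its substrate; the
N-terminal S/T of a fragment is the *used* cut site and does not count
against the missed-cleavage budget — only internal S/T (positions 2..n)
do. For a fragment with k internal sites and an unconstrained budget this
yields (k+1)(k+2)/2 products, which the tests check exactly. Protein
N-terminal Met is not stripped. Deduplication keys on the bare sequence;
modification states are generated at search time. Decoys are whole-protein
residue shuffles (seeded, `DECOY_` prefix); an optional mode preserves K/R
positions to match the target tryptic length distribution. Target and
decoy databases are deduplicated independently; a sequence occurring in
both is simply carried with both parent sets.

## Masses and fragments

All masses are monoisotopic (residue masses from pyteomics;
water 18.0105647, proton 1.0072765 Da). Glycans are compositions, not
structures: Hex 162.05282, HexNAc 203.07937, NeuAc 291.09542, Fuc
146.05791 Da per residue. Under HCD the O-glycan fragments preferentially,
so glycan delta masses ride on the precursor and on Y1 (peptide + one
HexNAc) but are excluded from b/y ions; non-glycan modifications shift b/y
normally. A `retain_glycans` switch exists for synthetic-data experiments.
Peptide masses are computed with exactly-rounded summation so the order of
a modification list can never change the result.

The oxonium reference table holds the standard HexNAc series (126.0550,
138.0550, 144.0655, 168.0655, 186.0761, 204.0867), Hex 163.0601, NeuAc
274.0921/292.1027 and HexHexNAc 366.1395. Which ions beyond the mandatory
204.0867 count as "others" is a package decision (the underlying method
does not enumerate them); the table is overridable from a two-column TSV.
The filter is presence-only at 10 ppm (relative to the theoretical m/z);
an optional relative-intensity floor defaults to 0.

## Scoring and FDR

The score is a binomial-tail matched-peak statistic: with n theoretical
b/y/Y0/Y1 ions at charges 1–2 and k matched within 20 ppm,
score = −log₁₀ P(X ≥ k), X ~ Binomial(n, p), where p is the chance-match
probability estimated from peak density
(`N_peaks · 2·tol_Da(median m/z) / span`, clamped to [1e-6, 0.5]).
This replaces a proprietary engine score; it is the q-value ranking, not
the absolute scale, that carries statistical meaning, and the calibration
tests assert exactly that. Defaults: precursor 10 ppm, fragment 20 ppm,
charges 2–6 (unknown charge tries all), ≤ 4 variable-mod placements.

Because glycan position affects no theoretical ion under HCD lability,
glycoforms are enumerated as composition multisets anchored
N-terminal-first rather than per-position placements — identical scores,
an order of magnitude fewer candidates, and consistent with the reporting
convention that a single glycan sits on the cleavage-defining N-terminal
S/T; multi-glycan forms are unlocalized beyond that first site.

Target and decoy candidates compete per scan (one best PSM per scan; ties
break toward the decoy, the conservative choice). q-values are the running
minimum of `#decoy(≥t)/max(1,#target(≥t))` from the bottom of the ranking;
reporting uses q ≤ 0.01. An FDR target of 0 is treated as the degenerate
accept-nothing boundary, since an estimated q of 0 only reflects the
absence of higher-scoring decoys. FDR is computed globally over the run
set, not per fraction.

The default variable-glycan set is the four-composition set
(Hex₁HexNAc₁, HexNAc₁, Hex₁HexNAc₂, Hex₂HexNAc₂): it covers the
generator's default mixture and the desialylated core-1 chemistry; studies
restricted to two glycans can trim it in the config.

## Quantification

Spectral counting between two pooled conditions. Totals for
normalization are per-sample counts over *all* accepted PSMs, not only
glyco rows. Peptide fold = summed normalized counts A / B;
condition-exclusive peptides get pseudo-folds 2.0 (A-only) / 0.5 (B-only)
so protein means remain defined. Protein fold is the plain arithmetic
mean of its peptide folds, pseudo values included. Significance requires
fold ≥ 2 or ≤ 0.5 *and* a raw PSM difference ≥ 10; raw (not normalized)
counts are used for the difference — the method statement is ambiguous on
this point and raw counts are the literal reading of "total number of
PSMs … summed". Peptide counts aggregate glycoforms and charge states of
one sequence by default (a per-glycoform mode exists); shared peptides
count toward every parent and are flagged.

## Site characterization

Sites are keyed (accession, start position); residue identity is checked
against the protein sequence. Motif windows are the 15 residues centered
on the site; sites within 7 residues of a terminus are excluded and
counted, never padded. Enrichment is a two-sided binomial test per
(residue, offset) against background frequencies taken from the non-center
window positions (user-overridable), with log₂ odds and Bonferroni
correction across the 20 × 14 grid — a defined, testable stand-in for
sequence-logo statistics. Tyr-centered sites are flagged and excluded from
the S/T logo by default. Relative position is 100·position/length.
Novelty calls against external site databases are supported only as a
generic comparison with a user-supplied reference TSV; no reference is
bundled, because such inventories are database-version-dependent.

## Synthetic data: what it emulates, and what it does not

The generator draws uniform-length random proteins (defaults: 40 proteins,
80–160 residues) with a combined S/T frequency of 0.12 (chosen as a
realistic vertebrate-proteome value), plants a glycosite at each S/T with
probability 0.3, and draws each site's composition from the default
mixture 69% Hex₁HexNAc₁ / 16% HexNAc₁ / 8% Hex₁HexNAc₂ / 7% Hex₂HexNAc₂ —
the core-1-dominated distribution typical of desialylated tissue data.
Abundance is log-normal per site-peptide (σ = 0.5) around a base Poisson
PSM rate of 3 per sample; a configurable fraction of proteins (default
10%, alternating up/down so sample totals stay roughly balanced) carries a
planted fold (default 4, reciprocal for the down set), applied to all
peptides of the protein. Spectra contain a sampled fraction (default
0.85) of theoretical b/y/Y0/Y1 ions at charges 1–2, the full oxonium
series for glycopeptides, 20 uniform noise peaks in 100–2000 m/z, and
Gaussian m/z error (σ = 2 ppm) on peaks and precursor; charges are drawn
from {2: 0.5, 3: 0.35, 4: 0.15}. Per-run background spectra of
non-glycosylated S/T-containing peptides (no glycan, no oxonium ions)
provide the non-site-specific fraction against which specificity is
measured. Everything is derived from one seed through independent
substreams, so FASTA, MGF and counts are byte-reproducible.

Deliberately not modeled: chromatography and retention time, isotope
envelopes, realistic intensity structure, co-isolation and chimeric
spectra, ETD fragments, and real protein sequence composition. Passing
recovery tests therefore demonstrates the correctness and calibration of
the pipeline's logic under its own assumptions — not identification
performance on real instrument data, where scoring and FDR behavior face
noise this generator does not produce.

The bundled demo protein in the examples is a synthetic sequence, not any
real database entry.

## Calibration and recovery experiments

Three experiments (in `oglyco.benchmarks`) double as the property suite:

- **Entrapment FDR check** — spectra generated from half the proteome,
  searched against the whole proteome plus decoys; a false match is any
  accepted PSM whose peptide differs from the generating peptide. Pooled
  over 10 seeds (16 proteins each), the false-match proportion at q ≤ 0.01
  must stay ≤ 5%.
- **Site recovery** — with perfect spectra (coverage 1, no jitter, no
  noise) recovered site positions must equal the planted, observable sites
  exactly; with default noise, recall ≥ 0.9. "Observable" means the site
  produced ≥ 1 spectrum: a Poisson count can be zero, and a site with no
  6–46-residue S/T-start peptide cannot be seen by construction, so those
  sites are excluded from the recall denominator rather than silently
  deflating it.
- **Quant recovery** — on true counts from the abundance model (base rate
  raised to 8 so proteins reach the ≥ 20 PSMs/condition regime the check
  is stated for), the median estimated fold of planted-fourfold proteins
  must lie within ±25% of 4, ≥ 90% of them must be flagged significant,
  and fold-1 proteins may be flagged at most 5% of the time. The median is
  the right central estimate here: single-protein estimates carry Poisson
  noise of order ±1 at these counts, and total-PSM normalization shrinks
  all folds slightly toward 1 when planted changes are not perfectly
  balanced.

Problem sizes throughout (tens of proteins, hundreds of spectra per run)
are the package's chosen desk-scale defaults; all experiments are seeded
and reproduce exactly.

## Known limitations

- The score is not calibrated across charge states or peptide lengths;
  only the decoy-based q-value layer is interpreted statistically.
- Glycan compositions are not structures; positional isomers and
  multi-glycan arrangements beyond the N-terminal site are unresolved.
- Open (wildcard) glycan search, semi-supervised rescoring, ETD/c-z
  scoring and site-probability models are out of scope.
- Spectra are assumed centroided; no deisotoping or charge deconvolution
  is performed.
- mzML reading covers the common MS2 layout (first precursor, first
  selected ion); vendor idiosyncrasies are untested.
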