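"""Monoisotopic mass arithmetic for O-glycopeptides.

Residue masses, glycan compositions, peptide modifications, precursor and
fragment m/z, and the diagnostic oxonium-ion reference table. All masses are
monoisotopic; average masses are unsupported.

Glycans are treated as labile under HCD: their delta masses ride on the
precursor (and on Y1, which retains a single HexNAc) but are excluded from
b/y backbone fragments by default.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from pyteomics import mass as _pmass

#: Monoisotopic mass of H2O (Da), added once per peptide chain.
WATER: float = 18.0105646837
#: Monoisotopic mass of a proton (Da), added once per charge.
PROTON: float = 1.00727646677

#: One-letter code -> monoisotopic residue mass (Da) for the 20 standard residues.
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Monosaccharide residue masses (Da): the mass each sugar adds to a glycan.
MONOSACCHARIDE_MASS: dict[str, float] = {
    "Hex": 162.05282342,
    "HexNAc": 203.07937252,
    "NeuAc": 291.09541651,
    "Fuc": 146.05790880,
}

HEXNAC_MASS: float = MONOSACCHARIDE_MASS["HexNAc"]


@dataclass(frozen=True)
class GlycanComposition:
    """A glycan as monosaccharide counts; structural isomers are not distinguished."""

    hex: int = 0
    hexnac: int = 0
    neuac: int = 0
    fuc: int = 0

    def __post_init__(self) -> None:
        counts = (self.hex, self.hexnac, self.neuac, self.fuc)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative monosaccharide count in {counts}")
        if not any(counts):
            raise ValueError("glycan composition must contain at least one sugar")

    @property
    def delta_mass(self) -> float:
        return (
            self.hex * MONOSACCHARIDE_MASS["Hex"]
            + self.hexnac * MONOSACCHARIDE_MASS["HexNAc"]
            + self.neuac * MONOSACCHARIDE_MASS["NeuAc"]
            + self.fuc * MONOSACCHARIDE_MASS["Fuc"]
        )

    def __str__(self) -> str:
        parts = []
        for name, n in (
            ("Hex", self.hex),
            ("HexNAc", self.hexnac),
            ("NeuAc", self.neuac),
            ("Fuc", self.fuc),
        ):
            if n:
                parts.append(f"{name}({n})")
        return "".join(parts)

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse a composition string like ``Hex(1)HexNAc(2)``."""
        import re

        counts = {"Hex": 0, "HexNAc": 0, "NeuAc": 0, "Fuc": 0}
        pos = 0
        for m in re.finditer(r"(Hex|HexNAc|NeuAc|Fuc)\((\d+)\)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse glycan composition {text!r}")
            counts[m.group(1)] += int(m.group(2))
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse glycan composition {text!r}")
        return cls(
            hex=counts["Hex"],
            hexnac=counts["HexNAc"],
            neuac=counts["NeuAc"],
            fuc=counts["Fuc"],
        )


@dataclass(frozen=True)
class ModificationSpec:
    """A non-glycan peptide modification.

    ``targets`` is the set of one-letter residue codes the modification may
    occupy; ``mode`` is ``"fixed"`` (applied exhaustively) or ``"variable"``.
    """

    name: str
    targets: frozenset[str]
    delta_mass: float
    mode: str = "variable"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be fixed or variable, got {self.mode!r}")


# the standard modification set: oxidation and guanidination variable,
# carbamidomethylation static
OXIDATION_M = ModificationSpec("Oxidation", frozenset("M"), 15.99491462, "variable")
GUANIDINATION_K = ModificationSpec("Guanidination", frozenset("K"), 42.02179806, "variable")
CARBAMIDOMETHYL_C = ModificationSpec("Carbamidomethyl", frozenset("C"), 57.02146372, "fixed")

#: Core mucin-type glycan compositions after desialylation (core 1 and related).
CORE_GLYCANS: tuple[GlycanComposition, ...] = (
    GlycanComposition(hex=1, hexnac=1),
    GlycanComposition(hexnac=1),
    GlycanComposition(hex=1, hexnac=2),
    GlycanComposition(hex=2, hexnac=2),
)

Modification = Union[ModificationSpec, GlycanComposition]


def is_glycan(mod: Modification) -> bool:
    return isinstance(mod, GlycanComposition)


_DEFAULT_OXONIUM: tuple[tuple[str, float], ...] = (
    ("HexNAc-C2H6O3", 126.0550),
    ("HexNAc-CH6O3", 138.0550),
    ("HexNAc-C2H4O2", 144.0655),
    ("HexNAc-2H2O", 168.0655),
    ("HexNAc-H2O", 186.0761),
    ("HexNAc", 204.0867),
    ("Hex", 163.0601),
    ("NeuAc-H2O", 274.0921),
    ("NeuAc", 292.1027),
    ("HexHexNAc", 366.1395),
)

#: m/z of the HexNAc oxonium ion, mandatory for a glycopeptide verdict.
MANDATORY_OXONIUM_MZ: float = 204.0867


@dataclass(frozen=True)
class OxoniumTable:
    """Diagnostic glycan fragment ions used to pre-filter glycopeptide spectra.

    The HexNAc oxonium at m/z 204.0867 is mandatory; the remaining entries are
    the standard HexNAc/Hex/NeuAc fragment series and may be overridden from a
    two-column TSV (label, m/z).
    """

    ions: tuple[tuple[str, float], ...] = _DEFAULT_OXONIUM
    mandatory_mz: float = MANDATORY_OXONIUM_MZ

    def __post_init__(self) -> None:
        mzs = [mz for _, mz in self.ions]
        if len(set(mzs)) != len(mzs):
            raise ValueError("oxonium table contains duplicate m/z entries")
        if any(mz <= 0 for mz in mzs):
            raise ValueError("oxonium m/z values must be positive")
        if not any(abs(mz - self.mandatory_mz) < 1e-6 for mz in mzs):
            raise ValueError(
                f"oxonium table must contain the mandatory ion at {self.mandatory_mz}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.ions)

    @classmethod
    def from_tsv(cls, path: str | Path, mandatory_mz: float = MANDATORY_OXONIUM_MZ) -> "OxoniumTable":
        ions = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                ions.append((row[0], float(row[1])))
        return cls(ions=tuple(ions), mandatory_mz=mandatory_mz)


ModPlacement = tuple[int, Modification]


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} at position {i}")


def peptide_mass(sequence: str, mods: Iterable[ModPlacement] = ()) -> float:
    """Monoisotopic mass (Da) of a peptide with positioned modifications.

    ``mods`` is an iterable of ``(position, modification)`` with 1-based
    positions; order never affects the result (mass additivity).
    """
    _check_sequence(sequence)
    terms = [WATER]
    terms.extend(RESIDUE_MASS[aa] for aa in sequence)
    deltas = []
    for pos, mod in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside peptide of length {len(sequence)}")
        deltas.append(mod.delta_mass)
    # exactly-rounded summation: the mod list order can never change the mass
    return math.fsum(terms + sorted(deltas))


def precursor_mz(mass: float, charge: int) -> float:
    """m/z of an ion of neutral ``mass`` carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON) / charge


def neutral_mass(mz: float, charge: int) -> float:
    """Inverse of :func:`precursor_mz`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def fragment_ions(
    sequence: str,
    mods: Iterable[ModPlacement] = (),
    kinds: Iterable[str] = ("b", "y", "Y0", "Y1"),
    charges: Sequence[int] = (1,),
    retain_glycans: bool = False,
) -> list[tuple[str, float]]:
    """Theoretical fragment m/z values for a (modified) peptide.

    b/y backbone ions carry non-glycan modifications but, reflecting the
    preferential loss of O-glycans under HCD, exclude glycan delta masses
    unless ``retain_glycans`` is set. Y0 is the intact peptide with all
    glycans lost; Y1 retains one HexNAc.
    """
    kinds = set(kinds)
    if not kinds:
        raise ValueError("at least one fragment kind is required")
    unknown = kinds - {"b", "y", "Y0", "Y1"}
    if unknown:
        raise ValueError(f"unknown fragment kinds: {sorted(unknown)}")
    _check_sequence(sequence)
    mods = list(mods)
    n = len(sequence)

    # per-residue delta masses, glycans separated out for HCD lability
    backbone_delta = [0.0] * (n + 1)  # 1-based
    glycan_total = 0.0
    for pos, mod in mods:
        if not 1 <= pos <= n:
            raise ValueError(f"modification position {pos} outside peptide of length {n}")
        if is_glycan(mod) and not retain_glycans:
            glycan_total += mod.delta_mass
        else:
            backbone_delta[pos] += mod.delta_mass

    out: list[tuple[str, float]] = []
    residue = [RESIDUE_MASS[aa] for aa in sequence]

    prefix = [0.0] * (n + 1)
    for i in range(1, n + 1):
        prefix[i] = prefix[i - 1] + residue[i - 1] + backbone_delta[i]

    for z in charges:
        if z < 1:
            raise ValueError(f"fragment charge must be >= 1, got {z}")
        zsuf = "+" * z
        if "b" in kinds:
            for i in range(1, n):
                out.append((f"b{i}{zsuf}", (prefix[i] + z * PROTON) / z))
        if "y" in kinds:
            for i in range(1, n):
                mass_y = prefix[n] - prefix[n - i] + WATER
                out.append((f"y{i}{zsuf}", (mass_y + z * PROTON) / z))
        peptide_y0 = prefix[n] + WATER
        if "Y0" in kinds:
            out.append((f"Y0{zsuf}", (peptide_y0 + z * PROTON) / z))
        if "Y1" in kinds:
            out.append((f"Y1{zsuf}", (peptide_y0 + HEXNAC_MASS + z * PROTON) / z))
    return out
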