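"""Run configuration: one YAML file carrying every pipeline parameter.

A bare config reproduces the reference settings: trypsin with 2 missed
cleavages then O-glycoprotease with 5, peptides of 6-46 residues, 10 ppm
precursor / 20 ppm fragment / 10 ppm oxonium tolerances, 1% FDR, and quant
thresholds of twofold change with a 10-PSM difference.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .masses import GlycanComposition, ModificationSpec, OxoniumTable
from .search import ModsConfig


@dataclass
class RunConfig:
    fasta: str = ""
    spectra: list[str] = field(default_factory=list)
    out_dir: str = "results"
    # digestion
    tryp_mc: int = 2
    oper_mc: int = 5
    min_len: int = 6
    max_len: int = 46
    proline_rule: bool = False
    # decoys
    decoy_seed: int = 0
    decoy_preserve_kr: bool = False
    # tolerances
    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    oxonium_tol_ppm: float = 10.0
    oxonium_min_rel_intensity: float = 0.0
    oxonium_table: str = ""  # optional TSV override (label, m/z)
    # search
    max_var_mods: int = 4
    charges: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    fdr: float = 0.01
    # modifications: name -> {targets, delta_mass, mode} plus glycan composition strings
    variable_glycans: list[str] = field(
        default_factory=lambda: [
            "Hex(1)HexNAc(1)",
            "HexNAc(1)",
            "Hex(1)HexNAc(2)",
            "Hex(2)HexNAc(2)",
        ]
    )
    variable_mods: list[dict] = field(
        default_factory=lambda: [
            {"name": "Oxidation", "targets": "M", "delta_mass": 15.99491462},
            {"name": "Guanidination", "targets": "K", "delta_mass": 42.02179806},
        ]
    )
    fixed_mods: list[dict] = field(
        default_factory=lambda: [
            {"name": "Carbamidomethyl", "targets": "C", "delta_mass": 57.02146372},
        ]
    )
    # quantification
    fold_threshold: float = 2.0
    psm_diff_threshold: int = 10
    sample_map: dict[str, str] = field(default_factory=dict)  # run -> condition (A|B)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("precursor_tol_ppm", self.precursor_tol_ppm),
            ("fragment_tol_ppm", self.fragment_tol_ppm),
            ("oxonium_tol_ppm", self.oxonium_tol_ppm),
            ("fold_threshold", self.fold_threshold),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def mods_config(self) -> ModsConfig:
        variable: list = [
            ModificationSpec(
                m["name"], frozenset(m["targets"]), float(m["delta_mass"]), "variable"
            )
            for m in self.variable_mods
        ]
        variable += [GlycanComposition.parse(g) for g in self.variable_glycans]
        fixed = tuple(
            ModificationSpec(
                m["name"], frozenset(m["targets"]), float(m["delta_mass"]), "fixed"
            )
            for m in self.fixed_mods
        )
        return ModsConfig(
            fixed=fixed, variable=tuple(variable), max_var_mods=self.max_var_mods
        )

    def oxonium(self) -> OxoniumTable:
        if self.oxonium_table:
            return OxoniumTable.from_tsv(self.oxonium_table)
        return OxoniumTable()
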