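"""Tandem-spectrum I/O, peak matching and the oxonium-ion prefilter.

MGF is the reference format (read and written through pyteomics); mzML is
supported behind the same reader contract. Spectra are assumed centroided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .masses import OxoniumTable

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with peaks sorted by m/z."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float | None = None
    source_run: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.scan_id}: precursor m/z must be > 0")
        if np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.scan_id}: negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class OxoniumVerdict:
    scan_id: str
    passed: bool
    matched_ions: tuple[str, ...]


def read_mgf(path: str | Path, source_run: str | None = None) -> list[Spectrum]:
    """Read an MGF file; every BEGIN/END IONS block yields one Spectrum."""
    run = source_run if source_run is not None else Path(path).stem
    out: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"index={i}"))
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"{path}: spectrum {title!r} has no PEPMASS")
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = None
            rt = params.get("rtinseconds")
            out.append(
                Spectrum(
                    scan_id=title,
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    retention_time=float(rt) if rt is not None else None,
                    source_run=run,
                )
            )
    if not out:
        logger.warning("no spectra found in %s", path)
    return out


def read_mzml(path: str | Path, source_run: str | None = None) -> list[Spectrum]:
    """Read MS2 spectra from an mzML file."""
    from pyteomics import mzml as _mzml

    run = source_run if source_run is not None else Path(path).stem
    out: list[Spectrum] = []
    with _mzml.read(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            charge = ion.get("charge state")
            scan = entry["scanList"]["scan"][0]
            rt = scan.get("scan start time")
            out.append(
                Spectrum(
                    scan_id=str(entry["id"]),
                    precursor_mz=float(ion["selected ion m/z"]),
                    precursor_charge=int(charge) if charge is not None else None,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    retention_time=float(rt) * 60.0 if rt is not None else None,
                    source_run=run,
                )
            )
    if not out:
        logger.warning("no MS2 spectra found in %s", path)
    return out


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Dispatch on ``format`` (``mgf`` | ``mzml``) or the file suffix."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "mgf":
        return read_mgf(path)
    if fmt == "mzml":
        return read_mzml(path)
    raise ValueError(f"unsupported spectrum format {fmt!r}")


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time:.3f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def match_peaks(
    spectrum: Spectrum, targets: Sequence[float], tol_ppm: float
) -> list[tuple[int, int]]:
    """Map each target m/z to the nearest peak within ``tol_ppm``.

    The tolerance is computed relative to the theoretical (target) m/z. One
    peak may satisfy multiple targets; unmatched targets are omitted.
    Returns ``(target index, peak index)`` pairs.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    out: list[tuple[int, int]] = []
    mz = spectrum.mz
    if mz.size == 0:
        return out
    for ti, target in enumerate(targets):
        tol = target * tol_ppm * 1e-6
        j = int(np.searchsorted(mz, target))
        best = None
        for k in (j - 1, j):
            if 0 <= k < mz.size:
                d = abs(mz[k] - target)
                if d <= tol and (best is None or d < best[0]):
                    best = (d, k)
        if best is not None:
            out.append((ti, best[1]))
    return out


def oxonium_filter(
    spectrum: Spectrum,
    table: OxoniumTable | None = None,
    tol_ppm: float = 10.0,
    min_rel_intensity: float = 0.0,
) -> OxoniumVerdict:
    """Presence-only oxonium-ion verdict at ``tol_ppm``.

    A spectrum passes when the mandatory HexNAc oxonium (m/z 204.0867) is
    present together with at least two other table ions. Intensities are
    ignored unless ``min_rel_intensity`` (fraction of the base peak) is set.
    """
    table = table or OxoniumTable()
    spec = spectrum
    if min_rel_intensity > 0 and spectrum.n_peaks:
        floor = min_rel_intensity * float(spectrum.intensity.max())
        keep = spectrum.intensity >= floor
        spec = Spectrum(
            scan_id=spectrum.scan_id,
            precursor_mz=spectrum.precursor_mz,
            precursor_charge=spectrum.precursor_charge,
            mz=spectrum.mz[keep],
            intensity=spectrum.intensity[keep],
            source_run=spectrum.source_run,
        )
    targets = [mz for _, mz in table.ions]
    matches = match_peaks(spec, targets, tol_ppm)
    matched = tuple(table.ions[ti][0] for ti, _ in matches)
    mandatory = any(
        abs(table.ions[ti][1] - table.mandatory_mz) < 1e-6 for ti, _ in matches
    )
    passed = mandatory and len(matched) >= 3
    return OxoniumVerdict(scan_id=spec.scan_id, passed=passed, matched_ions=matched)


def write_verdicts(verdicts: Iterable[OxoniumVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scan_id\tpassed\tmatched_ions\n")
        for v in verdicts:
            fh.write(f"{v.scan_id}\t{int(v.passed)}\t{';'.join(v.matched_ions)}\n")
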