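"""Authentic-standards library: records, CSV/MSP I/O and m/z-window lookup.

The library plays the role of an in-house database of authentic standards:
each record carries the metabolite's elemental formula, the adduct it is
observed as, an experimentally determined retention time and, where the
standard was fragmented, a reference HCD MS/MS spectrum.  Isomers (same
formula, different retention time) are first-class: several records may
share a theoretical m/z and are told apart chromatographically.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .chem import (
    AdductSpec,
    ElementalComposition,
    adduct_mz,
    get_adduct,
    parse_formula,
    ppm_error,
)

__all__ = [
    "ReferenceSpectrum",
    "MetaboliteRecord",
    "StandardsLibrary",
    "load_library",
    "save_library",
]

LIBRARY_COLUMNS = ["name", "formula", "adduct", "rt_min"]


@dataclass(frozen=True)
class ReferenceSpectrum:
    """A centroided MS/MS spectrum: (m/z, intensity) peaks plus precursor m/z."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float = float("nan")

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("spectrum must contain at least one peak")
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be positive")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @property
    def base_peak_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]


@dataclass(frozen=True)
class MetaboliteRecord:
    """One authentic standard: formula, adduct, retention time, optional MS2."""

    name: str
    formula: ElementalComposition
    adduct: AdductSpec
    rt: Optional[float]  # minutes; None => mass-only record
    ms2: Optional[ReferenceSpectrum] = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt is not None and self.rt <= 0:
            raise ValueError(f"record {self.name!r}: rt must be positive")

    @property
    def theoretical_mz(self) -> float:
        return adduct_mz(self.formula, self.adduct)

    @property
    def mass_only(self) -> bool:
        return self.rt is None


class StandardsLibrary:
    """A searchable collection of standards, indexed by theoretical m/z."""

    def __init__(self, records: Iterable[MetaboliteRecord]):
        records = list(records)
        names = [r.name for r in records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate record names: {sorted(dupes)}")
        self._records = sorted(records, key=lambda r: r.theoretical_mz)
        self._mz = [r.theoretical_mz for r in self._records]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[MetaboliteRecord]:
        return iter(self._records)

    def __getitem__(self, name: str) -> MetaboliteRecord:
        for rec in self._records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def records(self) -> list[MetaboliteRecord]:
        return list(self._records)

    def query_by_mz(self, mz: float, tol_ppm: float = 5.0) -> list[MetaboliteRecord]:
        """All records whose theoretical m/z is within ``tol_ppm`` of ``mz``.

        Returned in order of increasing absolute ppm error.
        """
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        half_width = mz * tol_ppm * 1e-6
        lo = bisect.bisect_left(self._mz, mz - half_width)
        hi = bisect.bisect_right(self._mz, mz + half_width)
        hits = [
            r
            for r in self._records[lo:hi]
            if abs(ppm_error(mz, r.theoretical_mz)) <= tol_ppm
        ]
        hits.sort(key=lambda r: abs(ppm_error(mz, r.theoretical_mz)))
        return hits


def _read_msp(path: "str | Path") -> dict[str, ReferenceSpectrum]:
    """Read an MSP spectral library into name -> ReferenceSpectrum."""
    from matchms.importing import load_from_msp

    spectra: dict[str, ReferenceSpectrum] = {}
    for sp in load_from_msp(str(path), metadata_harmonization=False):
        if sp is None or len(sp.peaks.mz) == 0:
            continue
        name = sp.get("compound_name") or sp.get("name")
        if not name:
            continue
        precursor = sp.get("precursor_mz")
        spectra[str(name)] = ReferenceSpectrum(
            peaks=tuple(zip(sp.peaks.mz.tolist(), sp.peaks.intensities.tolist())),
            precursor_mz=float(precursor) if precursor else float("nan"),
        )
    return spectra


def _write_msp(path: "str | Path", library: StandardsLibrary) -> None:
    from matchms import Spectrum
    from matchms.exporting import save_as_msp

    spectra = []
    for rec in library:
        if rec.ms2 is None:
            continue
        order = np.argsort(rec.ms2.mz)
        spectra.append(
            Spectrum(
                mz=rec.ms2.mz[order].astype(float),
                intensities=rec.ms2.intensity[order].astype(float),
                metadata={
                    "compound_name": rec.name,
                    "precursor_mz": rec.theoretical_mz,
                },
                metadata_harmonization=False,
            )
        )
    save_as_msp(spectra, str(path), style="nist")


def load_library(
    path: "str | Path", spectra_path: "str | Path | None" = None
) -> StandardsLibrary:
    """Load a standards library from CSV (+ optional MSP spectra, joined by name).

    The CSV must provide ``name, formula, adduct, rt_min``; an empty
    ``rt_min`` admits the record as mass-only.  Extra columns are kept as
    free-form tags.  Parse failures report the offending row number.
    """
    df = pd.read_csv(path, dtype={"name": str, "formula": str, "adduct": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library file missing required columns: {missing}")
    spectra = _read_msp(spectra_path) if spectra_path else {}
    extra_cols = [c for c in df.columns if c not in LIBRARY_COLUMNS]
    records = []
    for i, row in df.iterrows():
        try:
            formula = parse_formula(row["formula"])
            adduct = get_adduct(row["adduct"])
        except Exception as exc:
            raise ValueError(f"library row {i + 2} ({row['name']!r}): {exc}") from exc
        rt = None if pd.isna(row["rt_min"]) else float(row["rt_min"])
        tags = {c: row[c] for c in extra_cols if not pd.isna(row[c])}
        records.append(
            MetaboliteRecord(
                name=str(row["name"]),
                formula=formula,
                adduct=adduct,
                rt=rt,
                ms2=spectra.get(str(row["name"])),
                tags=tags,
            )
        )
    return StandardsLibrary(records)


def save_library(
    library: StandardsLibrary,
    path: "str | Path",
    spectra_path: "str | Path | None" = None,
) -> None:
    """Write the library back to CSV (and its spectra to MSP if requested)."""
    rows = []
    tag_cols: list[str] = []
    for rec in library:
        row = {
            "name": rec.name,
            "formula": rec.formula.hill_formula(),
            "adduct": rec.adduct.name,
            "rt_min": rec.rt,
        }
        for k, v in rec.tags.items():
            row[k] = v
            if k not in tag_cols:
                tag_cols.append(k)
        rows.append(row)
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS + tag_cols).to_csv(path, index=False)
    if spectra_path is not None:
        _write_msp(spectra_path, library)
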