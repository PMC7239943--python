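"""Extracted-ion chromatograms, peak detection/integration and in-source loss.

An anion-exchange run is represented as an ordered list of centroided MS1
scans.  The peak detector here is deliberately simple — apex detection with
valley-to-valley bounds and trapezoidal integration — and is documented as a
stand-in for vendor co-detection software; it is adequate for well-formed
chromatographic peaks such as those emitted by the synthetic run generator.

In-source fragmentation of multiply phosphorylated metabolites (e.g. loss of
PO4(3-) from ATP giving an ADP-mass satellite) produces satellite ions that
co-elute exactly with the parent, whereas the endogenous metabolite of the
same mass elutes minutes away.  :func:`assess_in_source_loss` quantifies the
co-eluting satellite as a fraction of the parent peak area and, across a
dilution series, checks the loss is linear in parent abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy import signal as _spsignal
from scipy import stats as _spstats

from .chem import ppm_error

if TYPE_CHECKING:  # pragma: no cover
    from .library import MetaboliteRecord

__all__ = [
    "Scan",
    "ScanSet",
    "Chromatogram",
    "PeakGroup",
    "extract_eic",
    "detect_and_integrate",
    "in_source_loss_fraction",
    "assess_in_source_loss",
    "InSourceLossResult",
]


@dataclass(frozen=True)
class Scan:
    """One centroided MS1 scan: retention time (minutes) plus peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class ScanSet:
    """An acquisition: scans ordered by strictly increasing retention time."""

    scans: tuple[Scan, ...]
    polarity: str = "-"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scans", tuple(self.scans))
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class Chromatogram:
    """An EIC: intensity vs retention time for one m/z window."""

    rt: np.ndarray
    intensity: np.ndarray
    target_mz: float
    tol_ppm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt", np.asarray(self.rt, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")


@dataclass(frozen=True)
class PeakGroup:
    """An integrated chromatographic peak."""

    apex_rt: float
    rt_start: float
    rt_end: float
    area: float
    height: float

    def __post_init__(self) -> None:
        if not (self.rt_start < self.apex_rt < self.rt_end):
            raise ValueError("peak bounds must bracket the apex")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("peak area and height must be positive")


def extract_eic(run: ScanSet, mz: float, tol_ppm: float = 5.0) -> Chromatogram:
    """Sum centroid intensities within ``tol_ppm`` of ``mz`` in each scan."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if len(run) == 0:
        raise ValueError("empty run")
    half_width = mz * tol_ppm * 1e-6
    rts = np.array([s.rt for s in run.scans])
    intensities = np.array(
        [
            s.intensity[(s.mz >= mz - half_width) & (s.mz <= mz + half_width)].sum()
            for s in run.scans
        ]
    )
    return Chromatogram(rt=rts, intensity=intensities, target_mz=mz, tol_ppm=tol_ppm)


def detect_and_integrate(
    chrom: Chromatogram,
    min_height: float = 0.0,
    min_points: int = 3,
    baseline_frac: float = 0.01,
) -> list[PeakGroup]:
    """Detect local-maximum peaks and integrate them valley-to-valley.

    A peak's bounds extend from the apex to the nearest valley on each side,
    stopping early once intensity falls below ``baseline_frac`` of the apex.
    Area is by the trapezoidal rule over the bounds (intensity x minutes).
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    y = chrom.intensity
    if len(y) < min_points or np.all(y <= 0):
        return []
    apex_idx, _ = _spsignal.find_peaks(y, height=max(min_height, 0.0) or None)
    peaks = []
    for apex in apex_idx:
        floor = baseline_frac * y[apex]
        left = apex
        while left > 0 and y[left - 1] < y[left] and y[left - 1] > floor:
            left -= 1
        if left > 0 and y[left - 1] <= floor:
            left -= 1
        right = apex
        while right < len(y) - 1 and y[right + 1] < y[right] and y[right + 1] > floor:
            right += 1
        if right < len(y) - 1 and y[right + 1] <= floor:
            right += 1
        if right - left + 1 < min_points:
            continue
        area = float(np.trapezoid(y[left : right + 1], chrom.rt[left : right + 1]))
        if area <= 0:
            continue
        peaks.append(
            PeakGroup(
                apex_rt=float(chrom.rt[apex]),
                rt_start=float(chrom.rt[left]),
                rt_end=float(chrom.rt[right]),
                area=area,
                height=float(y[apex]),
            )
        )
    return peaks


@dataclass(frozen=True)
class InSourceLossResult:
    """Per-run satellite/parent area fractions and their dilution linearity."""

    fractions: tuple[Optional[float], ...]
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None


def _nearest_peak(
    peaks: Sequence[PeakGroup], rt: float, rt_tol: float
) -> Optional[PeakGroup]:
    candidates = [p for p in peaks if abs(p.apex_rt - rt) <= rt_tol]
    return min(candidates, key=lambda p: abs(p.apex_rt - rt)) if candidates else None


def in_source_loss_fraction(
    run: ScanSet,
    parent: "MetaboliteRecord",
    satellite_mz: float,
    rt_tol: float = 0.1,
    tol_ppm: float = 5.0,
    min_height: float = 0.0,
) -> Optional[float]:
    """Co-eluting satellite area as a fraction of the parent peak area.

    Only a satellite apex within ``rt_tol`` minutes of the *parent's* apex
    counts: a chromatographically resolved peak at the satellite m/z (the
    endogenous metabolite) contributes zero.  Returns None when the parent
    peak itself is absent.
    """
    if parent.rt is None:
        raise ValueError("parent record must have a retention time")
    parent_peaks = detect_and_integrate(
        extract_eic(run, parent.theoretical_mz, tol_ppm), min_height=min_height
    )
    parent_peak = _nearest_peak(parent_peaks, parent.rt, max(rt_tol, 0.5))
    if parent_peak is None:
        return None
    sat_peaks = detect_and_integrate(
        extract_eic(run, satellite_mz, tol_ppm), min_height=min_height
    )
    sat_peak = _nearest_peak(sat_peaks, parent_peak.apex_rt, rt_tol)
    if sat_peak is None:
        return 0.0
    return sat_peak.area / parent_peak.area


def assess_in_source_loss(
    runs: Sequence[ScanSet],
    parent: "MetaboliteRecord",
    satellite_mz: float,
    rt_tol: float = 0.1,
    tol_ppm: float = 5.0,
) -> InSourceLossResult:
    """Quantify in-source neutral loss per run and its linearity across runs.

    Across a dilution series (>= 3 runs with detectable parent), satellite
    area is regressed on parent area; a high coefficient of determination
    indicates the loss is proportional to concentration and hence does not
    distort relative quantification.
    """
    fractions: list[Optional[float]] = []
    parent_areas, satellite_areas = [], []
    for run in runs:
        frac = in_source_loss_fraction(run, parent, satellite_mz, rt_tol, tol_ppm)
        fractions.append(frac)
        if frac is None:
            continue
        parent_peaks = detect_and_integrate(
            extract_eic(run, parent.theoretical_mz, tol_ppm)
        )
        peak = _nearest_peak(parent_peaks, parent.rt, max(rt_tol, 0.5))
        parent_areas.append(peak.area)
        satellite_areas.append(frac * peak.area)
    slope = intercept = r_squared = None
    if len(parent_areas) >= 3:
        fit = _spstats.linregress(parent_areas, satellite_areas)
        slope, intercept, r_squared = fit.slope, fit.intercept, fit.rvalue**2
    return InSourceLossResult(
        fractions=tuple(fractions),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
    )
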