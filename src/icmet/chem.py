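"""Elemental formulas, monoisotopic masses, adduct m/z and isotope envelopes.

The mass and abundance tables are pinned (``data/isotopes.csv``,
CODATA-2018 masses / CIAAW-2021 representative abundances) so that every
theoretical quantity in the package is reproducible to the stated decimal
places.  Negative-mode electrospray deprotonation removes a proton, not a
hydrogen atom: the departing H leaves its electron behind, so the [M-H]-
mass delta is ``-(m_H - m_e) = -1.00727645...`` Da.

Isotope envelopes are aggregated by nominal mass shift (M, M+1, M+2, ...),
which is what an orbitrap operated at ~70k resolution actually resolves;
fine structure within a shift bin is summed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ElementalComposition",
    "AdductSpec",
    "IsotopeEnvelope",
    "ADDUCTS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "theoretical_envelope",
    "envelope_similarity",
]

ELECTRON_MASS = 0.000548579909065  # Da, CODATA 2018
PROTON_MASS = 1.00727646688  # Da

# average spacing between adjacent isotopologue bins; the 13C-12C difference
# dominates for CHNOPS metabolites
_ISOTOPE_SPACING = 1.00335483507


class FormulaError(ValueError):
    """Raised for unparsable or chemically invalid formula strings."""


def _load_isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    table: dict[str, list[tuple[int, float, float]]] = {}
    ref = resources.files("icmet.data").joinpath("isotopes.csv")
    with ref.open() as fh:
        for row in csv.DictReader(
            r for r in fh if not r.startswith("#")
        ):
            table.setdefault(row["element"], []).append(
                (int(row["mass_shift"]), float(row["mass"]), float(row["abundance"]))
            )
    for isotopes in table.values():
        isotopes.sort()
    return table


ISOTOPES: dict[str, list[tuple[int, float, float]]] = _load_isotope_table()
#: monoisotopic (lightest-isotope) mass per supported element
MONO_MASS: dict[str, float] = {el: iso[0][1] for el, iso in ISOTOPES.items()}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """A parsed chemical formula: element symbol -> atom count."""

    counts: dict[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts or all(n == 0 for n in self.counts.values()):
            raise FormulaError("composition must contain at least one atom")
        for el, n in self.counts.items():
            if el not in MONO_MASS:
                raise FormulaError(f"unsupported element {el!r}")
            if n < 0 or n != int(n):
                raise FormulaError(f"count for {el} must be a non-negative integer")

    def __str__(self) -> str:
        return self.hill_formula()

    def hill_formula(self) -> str:
        """Canonical Hill-order string: C, H, then other elements alphabetically."""
        items = {el: n for el, n in self.counts.items() if n > 0}
        ordered: list[str] = []
        for el in ("C", "H"):
            if el in items:
                ordered.append(el + (str(items[el]) if items[el] > 1 else ""))
                del items[el]
        for el in sorted(items):
            ordered.append(el + (str(items[el]) if items[el] > 1 else ""))
        return "".join(ordered)


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation adduct: name, signed mass delta (Da) and signed charge."""

    name: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")
        if not np.isfinite(self.mass_delta):
            raise ValueError("adduct mass delta must be finite")


#: minimal adduct set; negative mode is the working mode of the method
ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    "[M-2H]2-": AdductSpec("[M-2H]2-", -2 * PROTON_MASS, -2),
    "[M-3H]3-": AdductSpec("[M-3H]3-", -3 * PROTON_MASS, -3),
    "[M+Cl]-": AdductSpec("[M+Cl]-", MONO_MASS["Cl"] + ELECTRON_MASS, -1),
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS, 1),
}


def get_adduct(name_or_spec: "str | AdductSpec") -> AdductSpec:
    if isinstance(name_or_spec, AdductSpec):
        return name_or_spec
    try:
        return ADDUCTS[name_or_spec]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name_or_spec!r}; known: {sorted(ADDUCTS)}"
        ) from None


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Ordered isotopologue peaks as (m/z, abundance relative to base peak)."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("envelope must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        abund = [p[1] for p in self.peaks]
        if any(b <= 0 or b > 1 + 1e-12 for b in abund):
            raise ValueError("relative abundances must lie in (0, 1]")
        if max(abund) < 1 - 1e-9:
            raise ValueError("base peak (abundance 1.0) missing")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak m/z must be strictly increasing")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-style formula string such as ``"C6H13O9P"``.

    Multi-digit counts are supported; a missing count means 1.  Raises
    :class:`FormulaError` naming the offending token on bad input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in MONO_MASS:
            raise FormulaError(f"unknown element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Neutral monoisotopic mass: sum of counts x lightest-isotope masses."""
    return float(sum(n * MONO_MASS[el] for el, n in comp.counts.items()))


def adduct_mz(comp: ElementalComposition, adduct: "str | AdductSpec") -> float:
    """m/z of the adduct ion: (monoisotopic mass + mass delta) / |charge|."""
    spec = get_adduct(adduct)
    return (monoisotopic_mass(comp) + spec.mass_delta) / abs(spec.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def _element_shift_distribution(element: str, count: int, n_bins: int) -> np.ndarray:
    """Abundance distribution over nominal mass shifts for ``count`` atoms."""
    single = np.zeros(n_bins)
    for shift, _mass, abundance in ISOTOPES[element]:
        if shift < n_bins:
            single[shift] += abundance
    # exponentiate the per-atom polynomial by repeated convolution-squaring
    result = np.zeros(n_bins)
    result[0] = 1.0
    base = single
    k = count
    while k:
        if k & 1:
            result = np.convolve(result, base)[:n_bins]
        k >>= 1
        if k:
            base = np.convolve(base, base)[:n_bins]
    return result


def theoretical_envelope(
    comp: ElementalComposition,
    adduct: "str | AdductSpec" = "[M-H]-",
    n_peaks: int = 3,
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of the adduct ion, binned by mass shift.

    Peak k sits at ``(M + delta + k*1.003355)/|z|``; abundances are the
    exact polynomial expansion of the elemental isotope distributions,
    aggregated per nominal shift and normalised to the base peak.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    spec = get_adduct(adduct)
    dist = np.zeros(n_peaks)
    dist[0] = 1.0
    for el, n in comp.counts.items():
        if n:
            dist = np.convolve(dist, _element_shift_distribution(el, n, n_peaks))[
                :n_peaks
            ]
    dist = dist / dist.max()
    base_mz = adduct_mz(comp, spec)
    z = abs(spec.charge)
    peaks = tuple(
        (base_mz + k * _ISOTOPE_SPACING / z, float(a))
        for k, a in enumerate(dist)
        if a > 0
    )
    return IsotopeEnvelope(peaks)


def envelope_similarity(
    observed: IsotopeEnvelope,
    theoretical: IsotopeEnvelope,
    n_compare: int = 3,
    floor: float = 0.01,
) -> float:
    """Abundance agreement between observed and theoretical envelopes.

    Score = 1 - mean over the first ``n_compare`` isotopologue positions of
    ``|obs - theo| / max(theo, floor)``, clipped to [0, 1].  A missing
    observed position counts as abundance 0.  The floor guards against
    division blow-up on near-absent theoretical peaks; both knobs are
    surfaced in the identification criteria config.
    """
    k = min(n_compare, len(theoretical.peaks))
    theo = theoretical.abundance[:k]
    obs = np.zeros(k)
    obs_ab = observed.abundance
    obs[: min(k, len(obs_ab))] = obs_ab[:k]
    deviation = np.abs(obs - theo) / np.maximum(theo, floor)
    return float(np.clip(1.0 - deviation.mean(), 0.0, 1.0))
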