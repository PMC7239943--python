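"""Ground-truth synthetic IC-MS data: libraries, feature tables and scan sets.

The generator emulates the statistical structure of an anion-exchange
untargeted experiment: library compounds with distinct retention times in a
1-30 min gradient, observed m/z perturbed by Gaussian ppm error (default sd
1.5 ppm, well inside the 5 ppm identification gate), retention-time jitter
(default sd 5 s against the 30 s gate), right-skewed lognormal abundances
parameterised by a %CV, group effects as multiplicative fold changes, pooled
QC replicates built as near-noiseless mixtures of all samples, and decoy
features displaced > 20 ppm from every library mass.  The default design is
two groups of nine replicates.

Every dataset is exactly reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .chem import ElementalComposition, IsotopeEnvelope, theoretical_envelope
from .library import MetaboliteRecord, ReferenceSpectrum, StandardsLibrary
from .chem import ADDUCTS
from .preprocess import FeatureTable
from .signal import Scan, ScanSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_library",
    "simulate_feature_table",
    "simulate_run",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for synthetic feature tables and runs."""

    n_features: int = 200
    n_identifiable: int = 50
    group_names: tuple[str, str] = ("mutant", "wildtype")
    group_sizes: tuple[int, int] = (9, 9)
    n_effect: int = 20  # features carrying a true fold change
    effect_fc: float = 4.0  # group_a mean / group_b mean
    effects: Optional[dict[int, float]] = None  # explicit feature-index -> FC
    intensity_median: float = 1.0e6
    intensity_spread_log10: float = 0.6  # between-feature baseline spread
    cv: float = 0.20  # within-group biological+technical CV
    mass_error_ppm_sd: float = 1.5
    rt_jitter_s_sd: float = 5.0
    qc_replicates: int = 3
    qc_cv: float = 0.05
    seed: int = 0
    # scan-set generation
    scan_interval_min: float = 0.05
    peak_sigma_min: float = 0.05
    rt_range: tuple[float, float] = (0.5, 31.5)

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least two samples")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n_identifiable > self.n_features:
            raise ValueError("n_identifiable cannot exceed n_features")


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic feature table."""

    feature_source: dict[str, Optional[str]]  # feature id -> record name / None
    true_fc: dict[str, float]
    group_means: dict[str, tuple[float, float]]
    envelopes: dict[str, IsotopeEnvelope] = field(default_factory=dict)
    ms2: dict[str, ReferenceSpectrum] = field(default_factory=dict)

    @property
    def identifiable(self) -> list[str]:
        return [f for f, src in self.feature_source.items() if src is not None]

    @property
    def effect_features(self) -> list[str]:
        return [f for f, fc in self.true_fc.items() if fc != 1.0]

    def to_json(self, path: "str | Path") -> None:
        payload = {
            "feature_source": self.feature_source,
            "true_fc": self.true_fc,
            "group_means": self.group_means,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


_ELEMENT_RANGES = {
    "C": (2, 12),
    "H": (3, 22),
    "N": (0, 3),
    "O": (1, 9),
    "P": (0, 2),
    "S": (0, 1),
}


def _random_formula(rng: np.random.Generator) -> ElementalComposition:
    counts = {
        el: int(rng.integers(lo, hi + 1)) for el, (lo, hi) in _ELEMENT_RANGES.items()
    }
    counts = {el: n for el, n in counts.items() if n > 0}
    counts.setdefault("C", 2)
    counts.setdefault("H", 4)
    counts.setdefault("O", 2)
    return ElementalComposition(counts)


def _random_ms2(
    rng: np.random.Generator, precursor_mz: float
) -> ReferenceSpectrum:
    n_peaks = int(rng.integers(3, 9))
    frag_mz = np.sort(rng.uniform(60.0, max(80.0, precursor_mz - 1.0), n_peaks))
    intensity = rng.lognormal(mean=np.log(1e4), sigma=1.0, size=n_peaks)
    return ReferenceSpectrum(
        peaks=tuple(zip(frag_mz.tolist(), intensity.tolist())),
        precursor_mz=precursor_mz,
    )


def simulate_library(n: int = 50, seed: int = 0) -> StandardsLibrary:
    """Generate ``n`` standards with distinct formulas/RTs and MS2 spectra.

    At least one isomer pair (identical formula, RT gap > 2 min) is always
    included so that chromatographic isomer discrimination is exercised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    adduct = ADDUCTS["[M-H]-"]
    formulas: list[ElementalComposition] = []
    seen: set[str] = set()
    # n-1 distinct formulas; the last record reuses formula 0 as an isomer
    while len(formulas) < max(n - 1, 1):
        comp = _random_formula(rng)
        key = comp.hill_formula()
        if key not in seen:
            seen.add(key)
            formulas.append(comp)
    if n > 1:
        formulas.append(formulas[0])
    # distinct retention times across 1-30 min with >2 min isomer separation
    rts = np.linspace(1.5, 29.5, len(formulas)) + rng.uniform(
        -0.2, 0.2, len(formulas)
    )
    rng.shuffle(rts)
    if n > 1 and abs(rts[-1] - rts[0]) <= 2.0:
        rts[-1] = rts[0] + 2.5 if rts[0] < 27.0 else rts[0] - 2.5
    records = []
    for i, (comp, rt) in enumerate(zip(formulas, rts)):
        name = f"met_{i + 1:03d}"
        rec = MetaboliteRecord(
            name=name, formula=comp, adduct=adduct, rt=float(round(rt, 3))
        )
        records.append(
            MetaboliteRecord(
                name=name,
                formula=comp,
                adduct=adduct,
                rt=float(round(rt, 3)),
                ms2=_random_ms2(rng, rec.theoretical_mz),
            )
        )
    return StandardsLibrary(records)


def _lognormal_matrix(
    rng: np.random.Generator, means: np.ndarray, cv: float, n_cols: int
) -> np.ndarray:
    """Lognormal draws with arithmetic mean ``means`` and fixed CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(means) - sigma**2 / 2.0
    return rng.lognormal(mean=mu[:, None], sigma=sigma, size=(len(means), n_cols))


def _decoy_mz(rng: np.random.Generator, library_mz: np.ndarray) -> float:
    """Random m/z at least 20 ppm away from every library mass."""
    while True:
        mz = float(rng.uniform(70.0, 800.0))
        if not len(library_mz) or np.min(np.abs(mz - library_mz) / library_mz) > 20e-6:
            return mz


def simulate_feature_table(
    lib: StandardsLibrary, config: SimulationConfig = SimulationConfig()
) -> tuple[FeatureTable, GroundTruth]:
    """Emit a feature table + ground truth mirroring the configured design.

    The first ``n_identifiable`` library records become observable features
    (m/z and RT perturbed inside the identification gates, with noisy
    observed isotope envelopes and MS2 spectra); the remainder are decoys.
    Effects are injected as multiplicative fold changes on group A.
    """
    rng = np.random.default_rng(config.seed)
    n_ident = min(config.n_identifiable, len(lib))
    records = lib.records[:n_ident]
    library_mz = np.array([r.theoretical_mz for r in lib.records])

    feature_ids: list[str] = []
    source: dict[str, Optional[str]] = {}
    envelopes: dict[str, IsotopeEnvelope] = {}
    ms2: dict[str, ReferenceSpectrum] = {}
    for rec in records:
        mz = rec.theoretical_mz * (1.0 + rng.normal(0, config.mass_error_ppm_sd) * 1e-6)
        rt = rec.rt + rng.normal(0, config.rt_jitter_s_sd) / 60.0
        fid = f"{rt:.2f}_{mz:.4f}"
        feature_ids.append(fid)
        source[fid] = rec.name
        theo = theoretical_envelope(rec.formula, rec.adduct, n_peaks=3)
        noisy = [(theo.peaks[0][0], 1.0)]
        for peak_mz, ab in theo.peaks[1:]:
            noisy.append((peak_mz, float(np.clip(ab * rng.normal(1.0, 0.02), 1e-6, 1.0))))
        envelopes[fid] = IsotopeEnvelope(tuple(noisy))
        if rec.ms2 is not None:
            obs_peaks = tuple(
                (pmz * (1.0 + rng.normal(0, 2.0) * 1e-6), inten)
                for pmz, inten in rec.ms2.peaks
            )
            ms2[fid] = ReferenceSpectrum(obs_peaks, rec.ms2.precursor_mz)
    for _ in range(config.n_features - n_ident):
        mz = _decoy_mz(rng, library_mz)
        rt = float(rng.uniform(1.0, 30.0))
        fid = f"{rt:.2f}_{mz:.4f}"
        feature_ids.append(fid)
        source[fid] = None

    # true per-feature fold changes: explicit map, or first n_effect features
    fc = np.ones(config.n_features)
    if config.effects is not None:
        for idx, value in config.effects.items():
            fc[idx] = value
    else:
        fc[: config.n_effect] = config.effect_fc

    baseline = 10 ** rng.normal(
        np.log10(config.intensity_median),
        config.intensity_spread_log10,
        config.n_features,
    )
    mean_b = baseline
    mean_a = baseline * fc
    n_a, n_b = config.group_sizes
    mat_a = _lognormal_matrix(rng, mean_a, config.cv, n_a)
    mat_b = _lognormal_matrix(rng, mean_b, config.cv, n_b)

    group_a, group_b = config.group_names
    sample_ids = [f"{group_a}_{i + 1}" for i in range(n_a)] + [
        f"{group_b}_{i + 1}" for i in range(n_b)
    ]
    intensities = pd.DataFrame(
        np.hstack([mat_a, mat_b]), index=feature_ids, columns=sample_ids
    )
    meta_rows = [(s, group_a, "1", "sample") for s in sample_ids[:n_a]] + [
        (s, group_b, "1", "sample") for s in sample_ids[n_a:]
    ]
    # pooled QC: equal-volume mixture of all samples, re-injected with small noise
    pooled = intensities.mean(axis=1).to_numpy()
    for q in range(config.qc_replicates):
        qc_id = f"QC_{q + 1}"
        intensities[qc_id] = _lognormal_matrix(rng, pooled, config.qc_cv, 1)[:, 0]
        meta_rows.append((qc_id, "QC", "1", "QC"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "group", "batch", "role"]
    ).set_index("sample")

    table = FeatureTable(intensities=intensities, meta=meta)
    truth = GroundTruth(
        feature_source=source,
        true_fc={fid: float(f) for fid, f in zip(feature_ids, fc)},
        group_means={
            fid: (float(a), float(b))
            for fid, a, b in zip(feature_ids, mean_a, mean_b)
        },
        envelopes=envelopes,
        ms2=ms2,
    )
    return table, truth


def simulate_run(
    lib: StandardsLibrary,
    config: SimulationConfig = SimulationConfig(),
    heights: Optional[dict[str, float]] = None,
    satellites: Optional[dict[str, tuple[float, float]]] = None,
    n_envelope_peaks: int = 3,
) -> ScanSet:
    """Generate a centroided negative-mode scan set for a standards library.

    Each compound elutes as a Gaussian profile centred on its library RT
    with isotope peaks from its theoretical envelope.  ``heights`` overrides
    apex heights per compound name; ``satellites`` maps a parent compound
    name to ``(satellite_mz, fraction)``, adding a co-eluting in-source-loss
    ion at that fraction of the parent's intensity.
    """
    rng = np.random.default_rng(config.seed)
    rt_lo, rt_hi = config.rt_range
    scan_rts = np.arange(rt_lo, rt_hi + 1e-9, config.scan_interval_min)
    compounds = []
    for rec in lib.records:
        if rec.rt is None:
            continue
        height = (heights or {}).get(
            rec.name, float(rng.lognormal(np.log(config.intensity_median), 0.5))
        )
        env = theoretical_envelope(rec.formula, rec.adduct, n_peaks=n_envelope_peaks)
        compounds.append((rec, height, env))
    scans = []
    sigma = config.peak_sigma_min
    for rt in scan_rts:
        mz_list: list[float] = []
        int_list: list[float] = []
        for rec, height, env in compounds:
            profile = height * np.exp(-0.5 * ((rt - rec.rt) / sigma) ** 2)
            if profile < 1.0:
                continue
            for peak_mz, ab in env.peaks:
                mz_list.append(peak_mz * (1.0 + rng.normal(0, 1.0) * 1e-6))
                int_list.append(profile * ab)
            sat = (satellites or {}).get(rec.name)
            if sat is not None:
                sat_mz, frac = sat
                mz_list.append(sat_mz * (1.0 + rng.normal(0, 1.0) * 1e-6))
                int_list.append(profile * frac)
        order = np.argsort(mz_list)
        scans.append(
            Scan(
                rt=float(rt),
                mz=np.asarray(mz_list)[order] if mz_list else np.empty(0),
                intensity=np.asarray(int_list)[order] if int_list else np.empty(0),
            )
        )
    return ScanSet(scans=tuple(scans), polarity="-")
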