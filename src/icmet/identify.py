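"""Four-criterion metabolite identification against an authentic-standards library.

An identification is accepted when the compound feature matches a standard on

1. accurate mass   — |ppm error| below ``mass_tol`` (default 5 ppm),
2. retention time  — |RT difference| below ``rt_tol`` (default 30 s),
3. isotope pattern — envelope similarity at least ``isotope_min`` (default 0.85),
4. MS/MS           — reference base peak plus at least ``frag_min_extra``
   additional fragments matched within ``frag_tol`` (default 12 ppm),

yielding tier ``identified``.  When no MS/MS was acquired for feature or
standard, criteria 1-3 alone yield ``identified_no_ms2``.  Features matching
no standard can still earn a ``putative`` tier against an offline candidate
table (mass < 5 ppm, isotope > 90%, fragments where possible); everything
else is ``unidentified``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import IsotopeEnvelope, envelope_similarity, ppm_error, theoretical_envelope
from .library import MetaboliteRecord, ReferenceSpectrum, StandardsLibrary, load_library
from .preprocess import FeatureTable, parse_feature_id

__all__ = [
    "IdentificationCriteria",
    "CompoundFeature",
    "CriterionEvidence",
    "IdentificationResult",
    "ExclusionRule",
    "match_fragments",
    "match_feature",
    "annotate_feature_table",
    "AnnotationSummary",
    "load_putative_candidates",
    "PHOSPHATE_EXCLUSION",
]

TIER_ORDER = ["identified", "identified_no_ms2", "putative", "unidentified"]


@dataclass(frozen=True)
class IdentificationCriteria:
    """Tolerances and thresholds for the four identification criteria."""

    mass_tol: float = 5.0  # ppm
    rt_tol: float = 30.0  # seconds
    isotope_min: float = 0.85  # envelope similarity fraction
    frag_tol: float = 12.0  # ppm for MS/MS fragment matching
    frag_min_extra: int = 2  # fragments beyond the base peak
    putative_isotope_min: float = 0.90  # stricter gate for putative tier
    isotope_n_compare: int = 3
    isotope_floor: float = 0.01

    def __post_init__(self) -> None:
        if min(self.mass_tol, self.rt_tol, self.frag_tol) <= 0:
            raise ValueError("tolerances must be positive")
        for v in (self.isotope_min, self.putative_isotope_min):
            if not 0 < v <= 1:
                raise ValueError("isotope thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class CompoundFeature:
    """An untargeted detection unit: RT/m-z pair with optional envelope and MS2."""

    feature_id: str
    rt: float
    mz: float
    observed_envelope: Optional[IsotopeEnvelope] = None
    ms2: Optional[ReferenceSpectrum] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")

    @classmethod
    def from_id(
        cls,
        feature_id: str,
        observed_envelope: Optional[IsotopeEnvelope] = None,
        ms2: Optional[ReferenceSpectrum] = None,
    ) -> "CompoundFeature":
        rt, mz = parse_feature_id(feature_id)
        return cls(feature_id, rt, mz, observed_envelope, ms2)


@dataclass(frozen=True)
class CriterionEvidence:
    """Measured values behind one candidate's pass/fail decisions."""

    candidate: str
    ppm: float
    rt_delta_s: Optional[float]
    isotope_score: Optional[float]
    frags_matched: Optional[int]
    mass_pass: bool
    rt_pass: bool
    isotope_pass: bool
    ms2_pass: Optional[bool]  # None => MS/MS not available on one side
    isotope_evaluable: bool = True


@dataclass(frozen=True)
class IdentificationResult:
    """Annotation decision for one feature: best match, tier and evidence."""

    feature: CompoundFeature
    tier: str
    best: Optional[MetaboliteRecord] = None
    evidence: Optional[CriterionEvidence] = None
    alternates: tuple[CriterionEvidence, ...] = ()
    flags: tuple[str, ...] = ()


def match_fragments(
    observed: ReferenceSpectrum,
    reference: ReferenceSpectrum,
    frag_tol: float = 12.0,
    frag_min_extra: int = 2,
) -> tuple[bool, int]:
    """Match a measured MS/MS spectrum against a reference HCD spectrum.

    The reference base peak must be matched, plus at least
    ``frag_min_extra`` further reference peaks, each within ``frag_tol`` ppm.
    Matching is greedy from the most intense reference peak down (ties to
    lower m/z); each observed peak is consumed by at most one reference peak.
    Returns (passed, number of reference peaks matched).
    """
    ref_order = sorted(
        range(len(reference.peaks)),
        key=lambda i: (-reference.peaks[i][1], reference.peaks[i][0]),
    )
    obs_mz = observed.mz
    used = np.zeros(len(obs_mz), dtype=bool)
    base_matched = False
    n_matched = 0
    for rank, i in enumerate(ref_order):
        ref_mz = reference.peaks[i][0]
        tol = ref_mz * frag_tol * 1e-6
        dist = np.abs(obs_mz - ref_mz)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tol:
            used[j] = True
            n_matched += 1
            if rank == 0:
                base_matched = True
    passed = base_matched and (n_matched - 1) >= frag_min_extra
    return passed, n_matched


def _score_candidate(
    feature: CompoundFeature,
    record: MetaboliteRecord,
    crit: IdentificationCriteria,
) -> CriterionEvidence:
    ppm = ppm_error(feature.mz, record.theoretical_mz)
    mass_pass = abs(ppm) <= crit.mass_tol

    rt_delta_s: Optional[float] = None
    rt_pass = False
    if record.rt is not None:
        rt_delta_s = (feature.rt - record.rt) * 60.0
        rt_pass = abs(rt_delta_s) <= crit.rt_tol

    isotope_score: Optional[float] = None
    isotope_evaluable = feature.observed_envelope is not None
    if isotope_evaluable:
        theo = theoretical_envelope(
            record.formula, record.adduct, n_peaks=crit.isotope_n_compare
        )
        isotope_score = envelope_similarity(
            feature.observed_envelope,
            theo,
            n_compare=crit.isotope_n_compare,
            floor=crit.isotope_floor,
        )
        isotope_pass = isotope_score >= crit.isotope_min
    else:
        # no measured envelope: criterion is not evaluable; the tier is
        # capped below "identified" by the caller via the evaluable flag
        isotope_pass = True

    frags_matched: Optional[int] = None
    ms2_pass: Optional[bool] = None
    if feature.ms2 is not None and record.ms2 is not None:
        ms2_pass, frags_matched = match_fragments(
            feature.ms2, record.ms2, crit.frag_tol, crit.frag_min_extra
        )

    return CriterionEvidence(
        candidate=record.name,
        ppm=ppm,
        rt_delta_s=rt_delta_s,
        isotope_score=isotope_score,
        frags_matched=frags_matched,
        mass_pass=mass_pass,
        rt_pass=rt_pass,
        isotope_pass=isotope_pass,
        ms2_pass=ms2_pass,
        isotope_evaluable=isotope_evaluable,
    )


def _tier_for(ev: CriterionEvidence) -> Optional[str]:
    """Library tier earned by one candidate's evidence, or None."""
    if not (ev.mass_pass and ev.rt_pass and ev.isotope_pass):
        return None
    if ev.ms2_pass is True and ev.isotope_evaluable:
        return "identified"
    if ev.ms2_pass is False:
        return None
    return "identified_no_ms2"


def load_putative_candidates(path: "str | Path | None" = None) -> StandardsLibrary:
    """Offline accurate-mass candidate table for the putative tier.

    The bundled default is a synthetic stand-in for a live structure-database
    query, holding formulas for plausible endogenous candidates.
    """
    if path is None:
        path = resources.files("icmet.data").joinpath(
            "putative_candidates_synthetic.csv"
        )
    return load_library(path)


def match_feature(
    feature: CompoundFeature,
    lib: StandardsLibrary,
    crit: IdentificationCriteria = IdentificationCriteria(),
    putative_lib: Optional[StandardsLibrary] = None,
) -> IdentificationResult:
    """Annotate one compound feature against the standards library.

    Candidates come from an m/z window query at ``mass_tol``; each is scored
    on all four criteria.  Passing candidates are ranked by (|RT delta|,
    |ppm|, isotope score descending).  If none passes and a putative
    candidate table is supplied, the putative rule (mass, isotope > 90%,
    fragments where possible) is applied to it.
    """
    candidates = lib.query_by_mz(feature.mz, crit.mass_tol)
    evidence = [_score_candidate(feature, rec, crit) for rec in candidates]
    passing = [(ev, _tier_for(ev)) for ev in evidence]
    passing = [(ev, tier) for ev, tier in passing if tier is not None]
    passing.sort(
        key=lambda et: (
            abs(et[0].rt_delta_s) if et[0].rt_delta_s is not None else np.inf,
            abs(et[0].ppm),
            -(et[0].isotope_score if et[0].isotope_score is not None else 0.0),
        )
    )
    if passing:
        best_ev, tier = passing[0]
        flags = () if best_ev.isotope_evaluable else ("no_observed_envelope",)
        return IdentificationResult(
            feature=feature,
            tier=tier,
            best=lib[best_ev.candidate],
            evidence=best_ev,
            alternates=tuple(ev for ev, _ in passing[1:]),
            flags=flags,
        )

    if putative_lib is not None:
        put = []
        for rec in putative_lib.query_by_mz(feature.mz, crit.mass_tol):
            ev = _score_candidate(feature, rec, crit)
            iso_ok = (
                ev.isotope_score is not None
                and ev.isotope_score >= crit.putative_isotope_min
            )
            frag_ok = ev.ms2_pass is not False  # "where possible"
            if ev.mass_pass and iso_ok and frag_ok:
                put.append(ev)
        if put:
            put.sort(key=lambda ev: abs(ev.ppm))
            return IdentificationResult(
                feature=feature,
                tier="putative",
                best=putative_lib[put[0].candidate],
                evidence=put[0],
                alternates=tuple(put[1:]),
            )

    return IdentificationResult(
        feature=feature, tier="unidentified", alternates=tuple(evidence)
    )


@dataclass(frozen=True)
class ExclusionRule:
    """Removes features before annotation (e.g. buffer-derived phosphate).

    Matches on feature id, or on an m/z (+- tol_ppm) and/or RT (+- rt_tol
    minutes) window; all supplied conditions must hold.
    """

    feature_id: Optional[str] = None
    mz: Optional[float] = None
    tol_ppm: float = 10.0
    rt: Optional[float] = None
    rt_tol: float = 0.1
    reason: str = "excluded"

    def matches(self, feature_id: str, rt: float, mz: float) -> bool:
        if self.feature_id is not None:
            return feature_id == self.feature_id
        ok = True
        if self.mz is not None:
            ok &= abs(ppm_error(mz, self.mz)) <= self.tol_ppm
        if self.rt is not None:
            ok &= abs(rt - self.rt) <= self.rt_tol
        return ok and (self.mz is not None or self.rt is not None)


#: buffer-derived phosphate and its ion clusters, which share one retention
#: time and would otherwise dominate multivariate models
PHOSPHATE_EXCLUSION = ExclusionRule(
    rt=15.28, rt_tol=0.05, reason="phosphate ion cluster (wash buffer)"
)


@dataclass(frozen=True)
class AnnotationSummary:
    """Row-wise annotation of a feature table plus removal log and tier counts."""

    table: pd.DataFrame
    results: tuple[IdentificationResult, ...]
    removed: tuple[tuple[str, str], ...]  # (feature_id, reason)
    skipped: tuple[str, ...]  # malformed ids

    @property
    def tier_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in TIER_ORDER}
        for res in self.results:
            counts[res.tier] += 1
        return counts


def annotate_feature_table(
    table: FeatureTable,
    lib: StandardsLibrary,
    crit: IdentificationCriteria = IdentificationCriteria(),
    exclusions: Sequence[ExclusionRule] = (),
    putative_lib: Optional[StandardsLibrary] = None,
    envelopes: Optional[dict[str, IsotopeEnvelope]] = None,
    ms2: Optional[dict[str, ReferenceSpectrum]] = None,
) -> AnnotationSummary:
    """Annotate every feature of a table; returns table + per-tier summary.

    ``envelopes`` and ``ms2`` optionally attach observed isotope envelopes /
    MS2 spectra by feature id.  Exclusion rules are applied first and each
    removal is logged with its reason.
    """
    envelopes = envelopes or {}
    ms2 = ms2 or {}
    removed: list[tuple[str, str]] = []
    skipped: list[str] = []
    results: list[IdentificationResult] = []
    rows = []
    for fid in table.features:
        try:
            rt, mz_val = parse_feature_id(fid)
        except ValueError:
            skipped.append(fid)
            continue
        rule = next((r for r in exclusions if r.matches(fid, rt, mz_val)), None)
        if rule is not None:
            removed.append((fid, rule.reason))
            continue
        feature = CompoundFeature(fid, rt, mz_val, envelopes.get(fid), ms2.get(fid))
        res = match_feature(feature, lib, crit, putative_lib)
        results.append(res)
        ev = res.evidence
        rows.append(
            {
                "feature_id": fid,
                "tier": res.tier,
                "best_name": res.best.name if res.best else None,
                "ppm": ev.ppm if ev else None,
                "rt_delta_s": ev.rt_delta_s if ev else None,
                "isotope_score": ev.isotope_score if ev else None,
                "frags_matched": ev.frags_matched if ev else None,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "tier",
            "best_name",
            "ppm",
            "rt_delta_s",
            "isotope_score",
            "frags_matched",
        ],
    ).set_index("feature_id")
    return AnnotationSummary(
        table=out,
        results=tuple(results),
        removed=tuple(removed),
        skipped=tuple(skipped),
    )
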