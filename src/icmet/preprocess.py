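"""Feature-table hygiene: missing-value filtering, normalisation, scaling, QC.

The central container is :class:`FeatureTable` — a compound-feature x sample
intensity matrix (features identified by "RT_mz" ids) with per-sample
metadata (group, batch, role).  Pooled-QC coefficient-of-variation reporting
follows the convention of counting features under 15% and 30% CV.

Order of operations in the pipeline is fixed: exclusions -> missing-value
filter -> normalisation -> statistics-specific scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "QCReport",
    "parse_feature_id",
    "load_feature_table",
    "filter_missing",
    "impute_missing",
    "normalize",
    "pareto_scale",
    "qc_cv_report",
]

META_COLUMNS = ["group", "batch", "role"]


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Split an "RT_mz" id (e.g. ``"14.33_146.0453"``) into (rt_min, mz)."""
    parts = str(feature_id).split("_")
    if len(parts) != 2:
        raise ValueError(f"malformed feature id {feature_id!r}; expected 'RT_mz'")
    try:
        rt, mz = float(parts[0]), float(parts[1])
    except ValueError:
        raise ValueError(f"malformed feature id {feature_id!r}") from None
    if mz <= 0:
        raise ValueError(f"feature id {feature_id!r} has non-positive m/z")
    return rt, mz


@dataclass(frozen=True)
class FeatureTable:
    """Feature x sample intensities plus per-sample metadata.

    ``intensities``: DataFrame indexed by feature id, one column per sample;
    NaN marks a missing value.  ``meta``: DataFrame indexed by sample id with
    columns group, batch and role ("sample" or "QC").
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.meta.index):
            raise ValueError("intensity columns and metadata rows must align")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if (self.intensities.fillna(0) < 0).any().any():
            raise ValueError("intensities must be non-negative")

    @property
    def features(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.intensities)

    def group_samples(self, group: str) -> list[str]:
        mask = (self.meta["group"] == group) & (self.meta["role"] == "sample")
        return list(self.meta.index[mask])

    @property
    def qc_samples(self) -> list[str]:
        return list(self.meta.index[self.meta["role"] == "QC"])

    @property
    def groups(self) -> list[str]:
        sel = self.meta.loc[self.meta["role"] == "sample", "group"]
        return list(dict.fromkeys(sel))

    def with_intensities(self, intensities: pd.DataFrame) -> "FeatureTable":
        return replace(self, intensities=intensities)

    def drop_features(self, feature_ids: list[str]) -> "FeatureTable":
        return self.with_intensities(self.intensities.drop(index=feature_ids))

    def to_csv(self, table_path: "str | Path", meta_path: "str | Path") -> None:
        self.intensities.rename_axis("feature_id").to_csv(table_path)
        self.meta.rename_axis("sample").to_csv(meta_path)


def load_feature_table(
    table_path: "str | Path", meta_path: "str | Path"
) -> FeatureTable:
    """Read intensities (first column feature_id) and sample metadata CSVs."""
    intens = pd.read_csv(table_path, index_col=0)
    intens.index = intens.index.astype(str)
    meta = pd.read_csv(meta_path, index_col=0)
    meta.index = meta.index.astype(str)
    if "batch" not in meta.columns:
        meta["batch"] = "1"
    return FeatureTable(intensities=intens, meta=meta)


def filter_missing(table: FeatureTable, min_presence: float = 0.8) -> FeatureTable:
    """Keep a feature iff it is present (non-missing, nonzero) in at least
    ``min_presence`` of the samples of at least one experimental group.

    This is the package's documented replacement for proprietary
    co-detection-based missing-value elimination.
    """
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must be in (0, 1]")
    present = table.intensities.notna() & (table.intensities > 0)
    keep = pd.Series(False, index=table.intensities.index)
    for group in table.groups:
        cols = table.group_samples(group)
        if cols:
            keep |= present[cols].mean(axis=1) >= min_presence
    return table.with_intensities(table.intensities.loc[keep])


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace remaining missing values by half the feature's minimum
    observed intensity (the usual small-value convention); features with no
    observed value at all become zero."""
    intens = table.intensities.copy()
    fill = intens.min(axis=1, skipna=True) / 2.0
    intens = intens.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return table.with_intensities(intens.fillna(0.0))


def normalize(
    table: FeatureTable,
    mode: str = "sum",
    scalars: Optional[pd.Series] = None,
) -> FeatureTable:
    """Normalise sample columns.

    ``sum``: divide each column by its total ion signal, then rescale to the
    median column total so intensities stay on the original scale ("normalise
    to all ions").  ``scalar``: divide each column by a supplied positive
    per-sample factor (e.g. total DNA content).
    """
    intens = table.intensities
    if mode == "sum":
        totals = intens.sum(axis=0, skipna=True)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"zero total ion signal in samples: {bad}")
        out = intens / totals * float(np.median(totals))
    elif mode == "scalar":
        if scalars is None:
            raise ValueError("scalar mode requires per-sample factors")
        scalars = scalars.reindex(intens.columns)
        if scalars.isna().any() or (scalars <= 0).any():
            raise ValueError("scalar factors must be positive and cover all samples")
        out = intens / scalars
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return table.with_intensities(out)


def pareto_scale(matrix: "pd.DataFrame | FeatureTable") -> pd.DataFrame:
    """Pareto scaling per feature row: (x - mean) / sqrt(sd), sd with n-1.

    Intermediate between no scaling and unit-variance scaling: large fold
    changes are damped but not flattened.  Constant rows map to all-zero.
    """
    intens = matrix.intensities if isinstance(matrix, FeatureTable) else matrix
    if intens.shape[1] < 2:
        raise ValueError("Pareto scaling needs at least two samples")
    centered = intens.sub(intens.mean(axis=1), axis=0)
    sd = intens.std(axis=1, ddof=1)
    scaled = centered.div(np.sqrt(sd), axis=0)
    return scaled.where(sd > 0, 0.0)


@dataclass(frozen=True)
class QCReport:
    """Per-feature %CV across pooled-QC replicates, with threshold counts."""

    cv_percent: pd.Series
    n_features: int
    n_qc: int
    thresholds: tuple[float, ...] = (15.0, 30.0)

    @property
    def counts_below(self) -> dict[float, int]:
        return {t: int((self.cv_percent < t).sum()) for t in self.thresholds}

    def summary(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_qc_samples": self.n_qc,
            **{f"cv_below_{t:g}": n for t, n in self.counts_below.items()},
            "median_cv": float(self.cv_percent.median()),
        }


def qc_cv_report(
    table: FeatureTable, thresholds: tuple[float, ...] = (15.0, 30.0)
) -> QCReport:
    """%CV (100 * sd/mean) per feature over the pooled-QC columns."""
    qc_cols = table.qc_samples
    if len(qc_cols) < 2:
        raise ValueError("need at least two QC samples for a %CV report")
    qc = table.intensities[qc_cols]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    cv = (100.0 * sd / mean).where(mean > 0, np.inf)
    return QCReport(
        cv_percent=cv,
        n_features=table.n_features,
        n_qc=len(qc_cols),
        thresholds=tuple(thresholds),
    )
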