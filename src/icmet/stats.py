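"""Differential statistics: fold change / FDR volcano, PCA, PLS-DA, correlation.

Univariate analysis computes per-feature fold changes (group A mean over
group B mean) and two-sample tests with Benjamini-Hochberg FDR control;
the volcano rule (FC > 2, q < 0.05) selects enriched and depleted features.

The supervised model is two-class (or multi-class) PLS-DA on a dummy-coded
class matrix, with variable importance in the projection

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ),

where w_a are the unit-norm X-weights and SSY_a the class-matrix variance
explained by component a; sum_j VIP_j^2 = p by construction.  Model quality
is reported as R2 (explained class variance on the full fit), Q2
(1 - PRESS/TSS under leave-one-out refitting) and LOO classification
accuracy (argmax over predicted dummy columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .preprocess import FeatureTable

__all__ = [
    "bh_adjust",
    "univariate_table",
    "volcano_select",
    "pca_fit",
    "PCAResult",
    "plsda_fit",
    "PLSDAModel",
    "loocv_validate",
    "ValidationReport",
    "correlate_to_anchor",
    "CorrelationResult",
    "euclidean_distance_matrix",
]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving with the input; ``{q < alpha}`` reproduces the classic
    BH rejection set at every ``alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    # guard against float rounding pushing q a ULP below p
    return np.maximum(q, p)


_TESTS = {"welch", "student", "mannwhitney"}


def univariate_table(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    test: str = "welch",
    fc_thresh: float = 2.0,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Per-feature fold change (A/B), test p-value, BH q-value and direction.

    Expects normalised intensities.  A zero group-B mean leaves the fold
    change undefined (NaN) for that feature; such features never pass the
    volcano rule.  ``direction`` applies the volcano thresholds.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    cols_a = table.group_samples(group_a)
    cols_b = table.group_samples(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least two samples")
    a = table.intensities[cols_a].to_numpy(dtype=float)
    b = table.intensities[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b > 0, mean_a / mean_b, np.nan)
        log2fc = np.log2(fc)
    if test == "welch":
        p = spstats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit").pvalue
    elif test == "student":
        p = spstats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit").pvalue
    else:
        p = np.array(
            [
                spstats.mannwhitneyu(ra[~np.isnan(ra)], rb[~np.isnan(rb)]).pvalue
                for ra, rb in zip(a, b)
            ]
        )
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    direction = np.where(
        (q < q_thresh) & (fc > fc_thresh),
        "enriched",
        np.where((q < q_thresh) & (fc < 1 / fc_thresh), "depleted", "unchanged"),
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=table.intensities.index,
    )


def volcano_select(
    result: pd.DataFrame, fc_thresh: float = 2.0, q_thresh: float = 0.05
) -> tuple[list[str], list[str]]:
    """Apply the volcano rule; returns (enriched ids, depleted ids)."""
    fc, q = result["fold_change"], result["q"]
    enriched = list(result.index[(fc > fc_thresh) & (q < q_thresh)])
    depleted = list(result.index[(fc < 1 / fc_thresh) & (q < q_thresh)])
    return enriched, depleted


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca_fit(x: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of a samples x features matrix (columns are features)."""
    n_components = min(n_components, min(x.shape))
    model = PCA(n_components=n_components)
    scores = model.fit_transform(x.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=x.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=x.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def _dummy_code(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    y = np.zeros((len(groups), len(labels)))
    for i, g in enumerate(groups):
        y[i, labels.index(g)] = 1.0
    return y, labels


@dataclass(frozen=True)
class PLSDAModel:
    """A fitted PLS-DA model with VIP scores."""

    n_components: int
    class_labels: list[str]
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components (X loadings)
    weights: pd.DataFrame  # features x components (unit-norm X weights)
    vip: pd.Series  # per-feature VIP
    r2: float  # explained class-matrix variance
    _pls: PLSRegression = field(repr=False, compare=False)

    def predict_class(self, x: pd.DataFrame) -> list[str]:
        pred = self._pls.predict(x.to_numpy(dtype=float))
        return [self.class_labels[i] for i in np.argmax(pred, axis=1)]


def _vip_scores(pls: PLSRegression) -> np.ndarray:
    w = pls.x_weights_  # p x A, unit-norm columns
    t = pls.x_scores_  # n x A
    q = pls.y_loadings_  # k x A
    ssy = np.sum(t**2, axis=0) * np.sum(q**2, axis=0)  # per-component SSY
    p = w.shape[0]
    return np.sqrt(p * (w**2 @ ssy) / ssy.sum())


def plsda_fit(
    x: pd.DataFrame, groups: Sequence[str], n_components: int = 2
) -> PLSDAModel:
    """Fit PLS-DA on a samples x features matrix with class labels.

    The class matrix is one-hot dummy coded; components are extracted by
    NIPALS-style PLS2 regression of the dummy matrix on the (already scaled)
    intensity matrix.
    """
    groups = list(groups)
    if len(groups) != len(x):
        raise ValueError("one group label per sample row required")
    y, labels = _dummy_code(groups)
    for lab in labels:
        if groups.count(lab) < 2:
            raise ValueError(f"class {lab!r} needs at least two samples")
    n_components = min(n_components, x.shape[1], len(x) - 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x.to_numpy(dtype=float), y)
    y_pred = pls.predict(x.to_numpy(dtype=float))
    ss_res = float(np.sum((y - y_pred) ** 2))
    ss_tot = float(np.sum((y - y.mean(axis=0)) ** 2))
    comp_names = [f"LV{i + 1}" for i in range(n_components)]
    return PLSDAModel(
        n_components=n_components,
        class_labels=labels,
        scores=pd.DataFrame(pls.x_scores_, index=x.index, columns=comp_names),
        loadings=pd.DataFrame(pls.x_loadings_, index=x.columns, columns=comp_names),
        weights=pd.DataFrame(pls.x_weights_, index=x.columns, columns=comp_names),
        vip=pd.Series(_vip_scores(pls), index=x.columns, name="vip"),
        r2=1.0 - ss_res / ss_tot,
        _pls=pls,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Leave-one-out cross-validation summary of a PLS-DA model."""

    r2: float
    q2: float
    accuracy: float
    n_components: int
    n_samples: int


def loocv_validate(
    x: pd.DataFrame, groups: Sequence[str], n_components: int = 2
) -> ValidationReport:
    """Leave-one-out validation: R2, Q2 = 1 - PRESS/TSS, and class accuracy.

    Each sample is held out in turn, the model refit on the remainder, and
    the held-out class scores predicted.  A training fold that loses an
    entire class is an error (the model would be degenerate).
    """
    groups = list(groups)
    n = len(x)
    if n < 3:
        raise ValueError("leave-one-out needs at least three samples")
    y, labels = _dummy_code(groups)
    full = plsda_fit(x, groups, n_components)
    press = 0.0
    correct = 0
    xv = x.to_numpy(dtype=float)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        train_groups = [groups[j] for j in keep]
        if len(set(train_groups)) < len(labels):
            raise ValueError("a training fold lost an entire class")
        ncomp = min(n_components, x.shape[1], len(keep) - 1)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(xv[keep], y[keep])
        pred = pls.predict(xv[i : i + 1])[0]
        press += float(np.sum((y[i] - pred) ** 2))
        if labels[int(np.argmax(pred))] == groups[i]:
            correct += 1
    tss = float(np.sum((y - y.mean(axis=0)) ** 2))
    return ValidationReport(
        r2=full.r2,
        q2=1.0 - press / tss,
        accuracy=correct / n,
        n_components=full.n_components,
        n_samples=n,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of every feature against an anchor feature."""

    anchor: str
    r: pd.Series
    r_thresh: float

    @property
    def positive(self) -> list[str]:
        passing = self.r[(self.r >= self.r_thresh) & (self.r.index != self.anchor)]
        return list(passing.sort_values(ascending=False).index)

    @property
    def negative(self) -> list[str]:
        passing = self.r[self.r <= -self.r_thresh]
        return list(passing.sort_values().index)


def correlate_to_anchor(
    table: FeatureTable, anchor: str, r_thresh: float = 0.8
) -> CorrelationResult:
    """Pearson r of every feature against the anchor feature across samples.

    Used to find features co-varying (positively or negatively) with a
    headline metabolite such as 2-hydroxyglutarate.
    """
    if anchor not in table.intensities.index:
        raise KeyError(f"anchor feature {anchor!r} not in table")
    cols = [s for s in table.samples if table.meta.loc[s, "role"] == "sample"]
    mat = table.intensities[cols].to_numpy(dtype=float)
    anchor_vec = table.intensities.loc[anchor, cols].to_numpy(dtype=float)
    if np.ptp(anchor_vec) == 0:
        raise ValueError("anchor feature is constant; correlation undefined")
    centered = mat - mat.mean(axis=1, keepdims=True)
    av = anchor_vec - anchor_vec.mean()
    denom = np.sqrt((centered**2).sum(axis=1) * (av**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, centered @ av / denom, np.nan)
    return CorrelationResult(
        anchor=anchor,
        r=pd.Series(r, index=table.intensities.index, name="r"),
        r_thresh=r_thresh,
    )


def euclidean_distance_matrix(x: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Euclidean distance matrix (heat-map substrate)."""
    d = squareform(pdist(x.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=x.index, columns=x.index)
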