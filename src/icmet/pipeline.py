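"""End-to-end orchestration: annotate -> preprocess -> statistics -> pathways.

A single YAML (or dict) configuration drives the whole analysis; every stage
writes its outputs into one run directory together with a manifest recording
the configuration, a hash of its semantically meaningful fields, and the
stage outputs.  Re-running with an identical configuration and inputs
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .identify import (
    ExclusionRule,
    IdentificationCriteria,
    annotate_feature_table,
)
from .library import load_library
from .pathways import analyze_pathways, load_pathways
from .preprocess import (
    filter_missing,
    impute_missing,
    load_feature_table,
    normalize,
    pareto_scale,
    qc_cv_report,
)
from .stats import (
    correlate_to_anchor,
    euclidean_distance_matrix,
    loocv_validate,
    pca_fit,
    plsda_fit,
    univariate_table,
    volcano_select,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("icmet")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    table: str
    metadata: str
    library: str
    group_a: str
    group_b: str
    spectra: Optional[str] = None
    pathways_gmt: Optional[str] = None
    pathways_edges: Optional[str] = None
    criteria: IdentificationCriteria = field(default_factory=IdentificationCriteria)
    exclusions: tuple[ExclusionRule, ...] = ()
    fc_thresh: float = 2.0
    q_thresh: float = 0.05
    r_thresh: float = 0.8
    min_presence: float = 0.8
    n_components: int = 2
    test: str = "welch"
    anchor: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fc_thresh, self.q_thresh, self.r_thresh, self.min_presence) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        crit = IdentificationCriteria(**raw.pop("criteria", {}))
        exclusions = tuple(
            ExclusionRule(**rule) for rule in raw.pop("exclusions", [])
        )
        return cls(criteria=crit, exclusions=exclusions, **raw)

    def validate_paths(self) -> None:
        required = {"table": self.table, "metadata": self.metadata, "library": self.library}
        optional = {
            "spectra": self.spectra,
            "pathways_gmt": self.pathways_gmt,
            "pathways_edges": self.pathways_edges,
        }
        for key, path in {**required, **optional}.items():
            if key in required and path is None:
                raise ValueError(f"config missing required path {key!r}")
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config path {key!r} does not exist: {path}")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: "str | Path") -> dict:
    """Run the full workflow; returns the manifest (also written as JSON).

    Stages: load + annotate against the standards library (exclusions
    applied and logged) -> missing-value filter, imputation and sum
    normalisation (+ QC %CV report) -> univariate volcano, Pareto-scaled
    PCA/PLS-DA with leave-one-out validation, optional anchor correlation,
    Euclidean distance matrix -> pathway enrichment + impact on the
    identified significant metabolites.  Any stage failure aborts with the
    stage name.
    """
    config.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stage = "load"
    try:
        table = load_feature_table(config.table, config.metadata)
        lib = load_library(config.library, config.spectra)

        stage = "annotate"
        annotation = annotate_feature_table(
            table, lib, config.criteria, exclusions=config.exclusions
        )
        annotation.table.to_csv(out / "annotated.csv")
        for fid, reason in annotation.removed:
            log.info("excluded feature %s: %s", fid, reason)
        excluded = [fid for fid, _ in annotation.removed] + list(annotation.skipped)
        if excluded:
            table = table.drop_features(excluded)
        manifest["stages"]["annotate"] = {
            "output": "annotated.csv",
            "tier_counts": annotation.tier_counts,
            "n_excluded": len(annotation.removed),
        }

        stage = "preprocess"
        n_before = table.n_features
        table = impute_missing(filter_missing(table, config.min_presence))
        log.info("missing-value filter: %d -> %d features", n_before, table.n_features)
        qc_summary = None
        if len(table.qc_samples) >= 2:
            qc_summary = qc_cv_report(table).summary()
            (out / "qc.json").write_text(json.dumps(qc_summary, indent=1))
        table = normalize(table, mode="sum")
        manifest["stages"]["preprocess"] = {
            "n_features": table.n_features,
            "qc": qc_summary,
        }

        stage = "stats"
        uni = univariate_table(
            table, config.group_a, config.group_b, config.test,
            config.fc_thresh, config.q_thresh,
        )
        if config.anchor is not None:
            uni["r_vs_anchor"] = correlate_to_anchor(
                table, config.anchor, config.r_thresh
            ).r
        uni.to_csv(out / "stats.csv")
        enriched, depleted = volcano_select(uni, config.fc_thresh, config.q_thresh)

        sample_cols = [
            s for s in table.samples if table.meta.loc[s, "role"] == "sample"
        ]
        scaled = pareto_scale(table.intensities[sample_cols]).T  # samples x features
        groups = [table.meta.loc[s, "group"] for s in sample_cols]
        pca = pca_fit(scaled, config.n_components)
        model = plsda_fit(scaled, groups, config.n_components)
        report = loocv_validate(scaled, groups, config.n_components)
        euclidean_distance_matrix(scaled).to_csv(out / "distance.csv")
        model_payload = {
            "r2": report.r2,
            "q2": report.q2,
            "accuracy": report.accuracy,
            "n_components": report.n_components,
            "explained_variance_pca": pca.explained_variance_ratio.tolist(),
            "vip_top": model.vip.sort_values(ascending=False).head(30).to_dict(),
        }
        (out / "model.json").write_text(json.dumps(model_payload, indent=1))
        manifest["stages"]["stats"] = {
            "outputs": ["stats.csv", "model.json", "distance.csv"],
            "n_enriched": len(enriched),
            "n_depleted": len(depleted),
            "loocv": {"r2": report.r2, "q2": report.q2, "accuracy": report.accuracy},
        }

        stage = "pathways"
        named = annotation.table.dropna(subset=["best_name"])
        universe = set(named["best_name"])
        significant = set(enriched) | set(depleted)
        hits = set(named.loc[named.index.isin(significant), "best_name"])
        if universe:
            pathways = load_pathways(config.pathways_gmt, config.pathways_edges)
            pw_table = analyze_pathways(pathways, universe, hits, seed=config.seed)
            pw_table.to_csv(out / "pathways.csv", index=False)
            manifest["stages"]["pathways"] = {
                "output": "pathways.csv",
                "n_pathways": len(pw_table),
                "n_universe": len(universe),
                "n_hits": len(hits),
            }
        else:
            manifest["stages"]["pathways"] = {"output": None, "n_universe": 0}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
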