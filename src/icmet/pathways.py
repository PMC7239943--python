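"""Pathway enrichment and topology-based impact over metabolite sets/graphs.

A pathway is a named set of metabolites plus an undirected reaction-adjacency
graph among them.  Two quantities are computed per pathway:

* **enrichment p** — either an exact hypergeometric over-representation test
  of the significant-metabolite hits, or a permutation version of the
  Goeman global-test quadratic statistic on member intensities;
* **impact** — the fraction of the pathway's total node importance carried
  by the hit members, with importance = betweenness centrality normalised by
  (n-1)(n-2)/2 within each connected component ("relative betweenness
  centrality").  A hub metabolite therefore moves impact far more than a
  peripheral one.

Member sets ship as GMT text, graphs as a pathway/node/node TSV edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as spstats

from .preprocess import FeatureTable, normalize, pareto_scale

__all__ = [
    "PathwayDefinition",
    "load_pathways",
    "pathway_impact",
    "hypergeometric_p",
    "globaltest_p",
    "pathway_enrichment",
    "analyze_pathways",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named metabolite set with an undirected graph over its members."""

    name: str
    members: frozenset[str]
    graph: nx.Graph = field(compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")
        extra = set(self.graph.nodes) - set(self.members)
        if extra:
            raise ValueError(f"pathway {self.name!r}: graph nodes not in members: {extra}")


def load_pathways(
    gmt_path: "str | Path | None" = None, edges_path: "str | Path | None" = None
) -> list[PathwayDefinition]:
    """Load pathway member sets (GMT) and member graphs (TSV edge list).

    With no arguments, the bundled curated mini-library of human central
    metabolism pathways is used.  GMT lines are ``name <TAB> description
    <TAB> member...``; edge lines are ``pathway <TAB> node_a <TAB> node_b``.
    """
    if gmt_path is None:
        gmt_path = resources.files("icmet.data").joinpath("pathways_curated.gmt")
    if edges_path is None:
        edges_path = resources.files("icmet.data").joinpath(
            "pathways_curated_edges.tsv"
        )
    edges: dict[str, list[tuple[str, str]]] = {}
    with open(edges_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pw, a, b = line.split("\t")
            edges.setdefault(pw, []).append((a, b))
    pathways = []
    with open(gmt_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, members = fields[0], [m for m in fields[2:] if m]
            graph = nx.Graph()
            graph.add_nodes_from(members)
            graph.add_edges_from(edges.get(name, []))
            pathways.append(
                PathwayDefinition(name=name, members=frozenset(members), graph=graph)
            )
    return pathways


def _relative_betweenness(graph: nx.Graph) -> dict[str, float]:
    """Betweenness centrality normalised per connected component."""
    importance: dict[str, float] = {}
    for nodes in nx.connected_components(graph):
        sub = graph.subgraph(nodes)
        importance.update(nx.betweenness_centrality(sub, normalized=True))
    return importance


def pathway_impact(pw: PathwayDefinition, hits: set[str]) -> float:
    """Fraction of total member importance carried by hit members.

    Importance is relative betweenness centrality; members absent from the
    graph carry zero importance.  An all-zero denominator (e.g. a pathway
    with no internal connectivity) yields impact 0.
    """
    importance = _relative_betweenness(pw.graph)
    total = sum(importance.get(m, 0.0) for m in pw.members)
    if total <= 0:
        return 0.0
    hit_sum = sum(importance.get(m, 0.0) for m in pw.members & hits)
    return hit_sum / total


def hypergeometric_p(universe: set[str], hits: set[str], pw: PathwayDefinition) -> float:
    """Exact upper-tail P(X >= observed pathway hits) over-representation test."""
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    members = pw.members & universe
    if not members:
        raise ValueError(f"pathway {pw.name!r} shares no members with the universe")
    k = len(members & hits)
    return float(spstats.hypergeom.sf(k - 1, len(universe), len(members), len(hits)))


def globaltest_p(
    member_matrix: pd.DataFrame,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value of the global-test quadratic score statistic.

    ``member_matrix`` is samples x pathway-members (already normalised and
    Pareto scaled).  The statistic is Q = || X' (y - mean(y)) ||^2 with y the
    group indicator; group labels are permuted ``n_permutations`` times and
    p = (1 + #{Q_perm >= Q_obs}) / (n_permutations + 1).
    """
    groups = list(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("global test here is two-group")
    x = member_matrix.to_numpy(dtype=float)
    y = np.array([1.0 if g == labels[1] else 0.0 for g in groups])

    def q_stat(yvec: np.ndarray) -> float:
        yc = yvec - yvec.mean()
        return float(np.sum((x.T @ yc) ** 2))

    q_obs = q_stat(y)
    rng = np.random.default_rng(seed)
    exceed = sum(
        q_stat(rng.permutation(y)) >= q_obs for _ in range(n_permutations)
    )
    return (1 + exceed) / (n_permutations + 1)


def pathway_enrichment(
    universe: set[str],
    hits: set[str],
    pw: PathwayDefinition,
    method: str = "hypergeometric",
    data: Optional[FeatureTable] = None,
    feature_names: Optional[dict[str, str]] = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Enrichment p-value for one pathway.

    ``hypergeometric``: exact over-representation of ``hits`` within the
    pathway against ``universe``.  ``globaltest_permutation``: association
    of member intensities with group labels; requires ``data`` (a feature
    table with exactly two sample groups) and ``feature_names`` mapping
    feature ids to metabolite names.  Intensities are sum-normalised and
    Pareto scaled before testing.
    """
    if method == "hypergeometric":
        return hypergeometric_p(universe, hits, pw)
    if method != "globaltest_permutation":
        raise ValueError(f"unknown enrichment method {method!r}")
    if data is None or feature_names is None:
        raise ValueError("globaltest mode requires intensity data and feature names")
    scaled = pareto_scale(normalize(data, mode="sum"))
    member_fids = [
        fid for fid, name in feature_names.items()
        if name in pw.members and fid in scaled.index
    ]
    if not member_fids:
        raise ValueError(f"pathway {pw.name!r}: no member features in the table")
    sample_cols = [s for s in data.samples if data.meta.loc[s, "role"] == "sample"]
    matrix = scaled.loc[member_fids, sample_cols].T
    groups = [data.meta.loc[s, "group"] for s in sample_cols]
    return globaltest_p(matrix, groups, n_permutations, seed)


def analyze_pathways(
    pathways: Sequence[PathwayDefinition],
    universe: set[str],
    hits: set[str],
    method: str = "hypergeometric",
    data: Optional[FeatureTable] = None,
    feature_names: Optional[dict[str, str]] = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment + impact table over a pathway library.

    Pathways sharing no member with the universe are skipped.  Output rows:
    pathway, n_members, n_hits, enrichment_p, neg_log10_p, impact — the
    coordinates of the classic significance-vs-impact pathway plot.
    """
    rows = []
    for pw in pathways:
        members_in = pw.members & universe
        if not members_in:
            continue
        p = pathway_enrichment(
            universe, hits, pw, method, data, feature_names, n_permutations, seed
        )
        rows.append(
            {
                "pathway": pw.name,
                "n_members": len(pw.members),
                "n_in_universe": len(members_in),
                "n_hits": len(pw.members & hits),
                "enrichment_p": p,
                "neg_log10_p": -np.log10(max(p, np.finfo(float).tiny)),
                "impact": pathway_impact(pw, hits),
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=[
                "pathway",
                "n_members",
                "n_in_universe",
                "n_hits",
                "enrichment_p",
                "neg_log10_p",
                "impact",
            ],
        )
        .sort_values("enrichment_p")
        .reset_index(drop=True)
    )
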