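"""Genus-level Spearman co-occurrence networks per tissue group.

Edges join genus pairs with |rho| >= 0.7 and two-sided p < 0.05 (raw, no
multiplicity correction, matching the stated edge rule).  Topology is
summarized by density, mean degree and mean local clustering; node
importance by degree, harmonic closeness and betweenness centrality.
Robust "core" nodes are those repeatedly ranked near the top of a composite
degree/closeness ranking across patient-level bootstrap rebuilds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .markers import cluster_bootstrap
from .tables import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class NodeFilters:
    min_prevalence: float = 0.2     # within-group presence fraction
    min_mean_abundance: float = 0.0  # within-group mean relative abundance


@dataclass
class CoNetwork:
    graph: nx.Graph
    group: str
    rho_min: float
    p_max: float
    n_samples: int
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)


def _spearman_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p-values."""
    n, m = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 0, x)
    z = ranks - ranks.mean(axis=0)
    sd = z.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    zn = z / safe
    rho = (zn.T @ zn) / n
    rho[:, sd == 0] = np.nan
    rho[sd == 0, :] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0 - 1e-12, 0.0, p)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return rho, p


def build_network(
    table: FeatureTable,
    metadata: CohortMetadata,
    group: str,
    rho_min: float = 0.7,
    p_max: float = 0.05,
    node_filters: NodeFilters | None = None,
    sample_ids: list[str] | None = None,
) -> CoNetwork:
    """Build the Spearman co-occurrence network for one tissue group.

    ``sample_ids`` overrides the group's sample set (used by the bootstrap,
    where resampled patients contribute duplicated samples).
    """
    node_filters = node_filters or NodeFilters()
    if sample_ids is None:
        meta = metadata.frame
        sample_ids = list(meta.loc[meta["tissue"] == group, "sample_id"])
    if len(sample_ids) < 5:
        raise ValueError(f"group {group!r} has fewer than 5 samples")
    data = table.data.loc[sample_ids]
    rel = data.div(data.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    prev = (data > 0).mean(axis=0)
    mean_ab = rel.mean(axis=0)
    keep = data.columns[
        (prev >= node_filters.min_prevalence) & (mean_ab >= node_filters.min_mean_abundance)
    ]
    rel = rel[keep]
    g = nx.Graph()
    for f in keep:
        g.add_node(f, prevalence=float(prev[f]), mean_abundance=float(mean_ab[f]))
    edge_rows = []
    if len(keep) >= 2:
        rho, p = _spearman_matrix(rel.to_numpy())
        idx = np.triu_indices(len(keep), k=1)
        for i, j in zip(*idx):
            r, pv = rho[i, j], p[i, j]
            if np.isfinite(r) and abs(r) >= rho_min and pv < p_max:
                a, b = keep[i], keep[j]
                sign = "positive" if r > 0 else "negative"
                g.add_edge(a, b, rho=float(r), p=float(pv), sign=sign)
                edge_rows.append(dict(node1=a, node2=b, rho=float(r), p=float(pv), sign=sign))
    edges = pd.DataFrame(edge_rows, columns=["node1", "node2", "rho", "p", "sign"])
    return CoNetwork(g, group, rho_min, p_max, len(sample_ids), edges)


def topology_metrics(net: CoNetwork) -> dict[str, float]:
    """Density, mean degree, and mean local clustering (degree<2 counts as 0)."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 1:
        raise ValueError("network has no nodes")
    density = 0.0 if n < 2 else 2.0 * e / (n * (n - 1))
    mean_degree = 2.0 * e / n
    clustering = float(nx.average_clustering(g)) if n else 0.0
    return {"density": float(density), "mean_degree": float(mean_degree),
            "clustering_coefficient": clustering}


def centralities(net: CoNetwork) -> pd.DataFrame:
    """Degree, harmonic-closeness (scaled by N-1) and betweenness centrality."""
    g = net.graph
    n = g.number_of_nodes()
    dc = nx.degree_centrality(g) if n > 1 else {v: 0.0 for v in g}
    harm = nx.harmonic_centrality(g)
    cc = {v: (harm[v] / (n - 1) if n > 1 else 0.0) for v in g}
    bc = nx.betweenness_centrality(g, normalized=True) if n > 2 else {v: 0.0 for v in g}
    return pd.DataFrame(
        {
            "node": list(g.nodes),
            "degree_centrality": [dc[v] for v in g],
            "closeness_centrality": [cc[v] for v in g],
            "betweenness_centrality": [bc[v] for v in g],
            "mean_abundance": [g.nodes[v].get("mean_abundance", np.nan) for v in g],
        }
    ).sort_values("degree_centrality", ascending=False, kind="stable").reset_index(drop=True)


@dataclass
class BootstrapStabilityParams:
    n_bootstrap: int = 500
    top_k: int = 10
    stability_min: float = 0.6
    seed: int = 0


def _composite_top_k(cent: pd.DataFrame, top_k: int) -> list[str]:
    """Top-k nodes by the mean of degree- and closeness-centrality ranks."""
    if cent.empty:
        return []
    dc_rank = cent["degree_centrality"].rank(ascending=False, method="average")
    cc_rank = cent["closeness_centrality"].rank(ascending=False, method="average")
    composite = (dc_rank + cc_rank) / 2.0
    order = composite.sort_values(kind="stable").index[:top_k]
    return list(cent.loc[order, "node"])


def bootstrap_stable_nodes(
    table: FeatureTable,
    metadata: CohortMetadata,
    group: str,
    params: BootstrapStabilityParams | None = None,
    rho_min: float = 0.7,
    p_max: float = 0.05,
    node_filters: NodeFilters | None = None,
) -> tuple[list[str], pd.Series]:
    """Per-node bootstrap recovery fraction in the composite top-k ranking."""
    params = params or BootstrapStabilityParams()
    meta = metadata.frame
    group_meta = meta.loc[meta["tissue"] == group]
    patients = pd.unique(group_meta["patient_id"])
    if len(patients) < 5:
        raise ValueError(f"group {group!r} has fewer than 5 patients")
    by_patient = group_meta.groupby("patient_id")["sample_id"].apply(list)
    counts: dict[str, int] = {f: 0 for f in table.feature_ids}
    n_empty = 0
    for bag in cluster_bootstrap(patients, params.n_bootstrap, seed=params.seed):
        samples: list[str] = []
        for pid in bag:
            samples.extend(by_patient[pid])
        try:
            net = build_network(
                table, metadata, group, rho_min=rho_min, p_max=p_max,
                node_filters=node_filters, sample_ids=samples,
            )
        except ValueError:
            n_empty += 1
            continue
        if net.graph.number_of_edges() == 0:
            n_empty += 1
            continue
        for node in _composite_top_k(centralities(net), params.top_k):
            counts[node] += 1
    if n_empty:
        logger.info("bootstrap_stable_nodes: %d iterations with empty networks", n_empty)
    stability = pd.Series(
        {f: c / params.n_bootstrap for f, c in counts.items()}, name="stability"
    ).sort_values(ascending=False, kind="stable")
    stable = list(stability.index[stability >= params.stability_min])
    return stable, stability
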