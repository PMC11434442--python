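"""Co-occurrence graph construction and the node/network metrics reported.

Edges require both gates: FDR-adjusted p below alpha AND |rho| at or above
the selected threshold (positive rho only by default, matching networks that
keep only significant positive correlations). Edge weight is |rho|; the sign
is kept as an attribute. Nodes are taxa with at least one retained edge;
isolated taxa are excluded unless requested.

Shortest-path metrics treat edges as unweighted: correlation magnitudes are
similarities, not distances, and converting them would impose an arbitrary
transform. Closeness uses Wasserman-Faust component scaling and betweenness
the standard 2/((n-1)(n-2)) normalization so that both live in [0, 1] on
disconnected graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from rhizonet.correlation import CorrelationSet
from rhizonet.errors import ValidationError

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "degree",
    "weighted_degree",
    "closeness",
    "betweenness",
    "clustering",
]


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_weighted_degree: float
    clustering_coefficient: float
    modularity: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_weighted_degree": self.average_weighted_degree,
            "clustering_coefficient": self.clustering_coefficient,
            "modularity": self.modularity,
        }


def build_network(
    cset: CorrelationSet,
    threshold: float,
    alpha: float = 0.01,
    positive_only: bool = True,
    phyla: pd.Series | None = None,
    mean_abundance: pd.Series | None = None,
    include_isolates: bool = False,
) -> nx.Graph:
    """Undirected weighted graph of taxa passing both significance gates."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    pairs = cset.pairs
    if pairs["p_adj"].isna().any():
        raise ValidationError("p_adj not populated; run adjust_fdr first")

    mask = (pairs["p_adj"] < alpha) & (pairs["rho"].abs() >= threshold)
    if positive_only:
        mask &= pairs["rho"] > 0
    kept = pairs[mask]

    g = nx.Graph()
    if include_isolates:
        g.add_nodes_from(cset.taxa)
    for row in kept.itertuples(index=False):
        g.add_edge(
            row.taxon_i,
            row.taxon_j,
            weight=abs(float(row.rho)),
            rho=float(row.rho),
            sign=1 if row.rho > 0 else -1,
        )
    if g.number_of_edges() == 0:
        logger.warning("build_network: no edges pass both gates")
    if phyla is not None:
        nx.set_node_attributes(
            g, {v: str(phyla.get(v, "Unclassified")) for v in g.nodes}, "phylum"
        )
    if mean_abundance is not None:
        nx.set_node_attributes(
            g,
            {v: float(mean_abundance.get(v, 0.0)) for v in g.nodes},
            "mean_relative_abundance",
        )
    g.graph["threshold"] = float(threshold)
    g.graph["alpha"] = float(alpha)
    g.graph["positive_only"] = bool(positive_only)
    return g


def degrees(g: nx.Graph) -> pd.Series:
    return pd.Series(dict(g.degree()), dtype=int).reindex(list(g.nodes))


def weighted_degrees(g: nx.Graph) -> pd.Series:
    return pd.Series(dict(g.degree(weight="weight")), dtype=float).reindex(list(g.nodes))


def closeness(g: nx.Graph) -> pd.Series:
    """Unweighted closeness with Wasserman-Faust component scaling.

    C(v) = ((r-1)/(n-1)) * ((r-1)/sum of distances within v's component),
    r = component size. Isolated nodes get 0.
    """
    vals = nx.closeness_centrality(g, wf_improved=True)
    return pd.Series(vals, dtype=float).reindex(list(g.nodes))


def betweenness(g: nx.Graph) -> pd.Series:
    """Unweighted shortest-path betweenness, normalized by 2/((n-1)(n-2))."""
    vals = nx.betweenness_centrality(g, normalized=True, weight=None)
    return pd.Series(vals, dtype=float).reindex(list(g.nodes))


def clustering_coefficients(g: nx.Graph) -> pd.Series:
    """Local clustering 2*tri(v)/(k(v)(k(v)-1)); 0 for degree < 2."""
    vals = nx.clustering(g, weight=None)
    return pd.Series(vals, dtype=float).reindex(list(g.nodes))


def mean_clustering(g: nx.Graph) -> float:
    """Network-level clustering = unweighted mean of local coefficients."""
    if g.number_of_nodes() == 0:
        return 0.0
    return float(clustering_coefficients(g).mean())


def transitivity(g: nx.Graph) -> float:
    """Global transitivity (triangle ratio); computed for reference only."""
    return float(nx.transitivity(g)) if g.number_of_nodes() else 0.0


def node_metrics(g: nx.Graph, partition: dict | None = None) -> pd.DataFrame:
    """Per-node metric table: degree, weighted degree, closeness, betweenness,
    local clustering, and (optionally) module id."""
    frame = pd.DataFrame(
        {
            "degree": degrees(g),
            "weighted_degree": weighted_degrees(g),
            "closeness": closeness(g),
            "betweenness": betweenness(g),
            "clustering": clustering_coefficients(g),
        }
    )
    frame.index.name = "taxon"
    if partition is not None:
        frame["module"] = pd.Series(partition).reindex(frame.index)
    return frame


def summarize(g: nx.Graph, modularity: float | None = None) -> NetworkSummary:
    """Network-level summary; average weighted degree is the node mean of
    strength (equivalently 2*sum(weights)/n)."""
    n = g.number_of_nodes()
    if n == 0:
        return NetworkSummary(0, 0, 0.0, 0.0, modularity)
    awd = float(weighted_degrees(g).mean())
    return NetworkSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        average_weighted_degree=awd,
        clustering_coefficient=mean_clustering(g),
        modularity=modularity,
    )
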