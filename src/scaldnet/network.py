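"""Windowed Pearson correlation networks over cluster means and metabolites.

Nodes are gene-cluster mean profiles and individual metabolites; an
undirected edge joins two nodes when the squared Pearson correlation of
their profiles over the chosen storage-day window reaches the threshold
(default r^2 >= 0.700, qualifying on magnitude regardless of sign).
Edges carry r, r^2 and the weight 1 - r^2 used by downstream layout and
shortest-path tools.  Correlations use replicate-level observations
within the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data import OmicsBlock
from .errors import ValidationError
from .multivariate import _pearson_with

logger = logging.getLogger(__name__)

R2_MIN = 0.700
TWO_MONTH_DAYS = (0, 7, 14, 28, 61)


@dataclass
class CorrelationNetwork:
    """Correlation graph over metabolites and gene-cluster profiles."""

    graph: nx.Graph
    window_label: str
    window_days: tuple[int, ...]
    excluded: list[str] = field(default_factory=list)  # constant profiles

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))


def cluster_node_name(cluster_id: int) -> str:
    return f"cluster_{cluster_id}"


def build_network(
    cluster_means: pd.DataFrame,
    metabolites: OmicsBlock,
    meta: pd.DataFrame,
    window: Sequence[int],
    r2_min: float = R2_MIN,
    label: str | None = None,
) -> CorrelationNetwork:
    """Build the correlation network for one storage-day window.

    ``cluster_means`` is clusters x samples; ``metabolites`` samples x
    metabolites; ``meta`` maps samples to storage days.  Profiles that
    are constant within the window are excluded from pairing (logged).
    """
    window = tuple(sorted(set(int(d) for d in window)))
    days_present = set(meta["day"])
    if not set(window) <= days_present:
        raise ValidationError(
            f"window days {sorted(set(window) - days_present)} not in the design"
        )
    sample_ids = list(meta.loc[meta["day"].isin(window), "sample_id"])
    if len(sample_ids) < 3:
        raise ValidationError("need at least 3 observations in the window")

    names: list[str] = []
    kinds: list[str] = []
    rows: list[np.ndarray] = []
    for cid in cluster_means.index:
        names.append(cluster_node_name(int(cid)))
        kinds.append("gene_cluster")
        rows.append(cluster_means.loc[cid, sample_ids].to_numpy(dtype=float))
    met_data = metabolites.data.loc[sample_ids]
    for mid in metabolites.variable_ids:
        names.append(str(mid))
        kinds.append("metabolite")
        rows.append(met_data[mid].to_numpy(dtype=float))

    mat = np.vstack(rows)
    sd = mat.std(axis=1)
    excluded = [n for n, s in zip(names, sd) if s == 0]
    if excluded:
        logger.warning(
            "excluding %d constant profile(s) in window %s: %s",
            len(excluded), window, ", ".join(excluded[:10]),
        )
    keep = sd > 0
    names_k = [n for n, k in zip(names, keep) if k]
    kinds_k = [k_ for k_, k in zip(kinds, keep) if k]
    mat = mat[keep]

    graph = nx.Graph()
    for n_, k_ in zip(names_k, kinds_k):
        graph.add_node(n_, kind=k_)
    if len(names_k) >= 2:
        corr = np.corrcoef(mat)
        r2 = corr**2
        iu, ju = np.triu_indices(len(names_k), k=1)
        for i, j in zip(iu, ju):
            if r2[i, j] >= r2_min:
                r = float(corr[i, j])
                graph.add_edge(
                    names_k[i],
                    names_k[j],
                    r=r,
                    r2=r * r,
                    weight=1.0 - r * r,
                )
    return CorrelationNetwork(
        graph=graph,
        window_label=label or f"days_{window[0]}-{window[-1]}",
        window_days=window,
        excluded=excluded,
    )


def first_neighbors(net: CorrelationNetwork, anchor: str) -> CorrelationNetwork:
    """Induced subnetwork on the anchor and its direct neighbors."""
    if anchor not in net.graph:
        raise ValidationError(
            f"anchor '{anchor}' not present in network '{net.window_label}'"
        )
    keep = {anchor} | set(net.graph.neighbors(anchor))
    sub = net.graph.subgraph(keep).copy()
    return CorrelationNetwork(
        graph=sub,
        window_label=f"{net.window_label}:first_neighbors({anchor})",
        window_days=net.window_days,
        excluded=list(net.excluded),
    )


def refine_members(
    gene_ids: Iterable[str],
    expression: OmicsBlock,
    anchor_trace: pd.Series,
    sample_ids: Sequence[str] | None = None,
    r2_min: float = R2_MIN,
) -> list[str]:
    """Keep only genes whose profile correlates (r^2 >= threshold) with
    the anchor metabolite trace over the window observations."""
    gene_ids = list(gene_ids)
    if sample_ids is None:
        sample_ids = list(anchor_trace.index)
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValidationError("empty observation window for refinement")
    y = anchor_trace.loc[sample_ids].to_numpy(dtype=float)
    if not gene_ids:
        return []
    M = expression.data.loc[sample_ids, gene_ids].to_numpy(dtype=float)
    r = _pearson_with(y, M)
    return [g for g, rv in zip(gene_ids, r) if rv * rv >= r2_min]


def node_metrics(net: CorrelationNetwork) -> pd.DataFrame:
    """Per-node degree, neighborhood connectivity and clustering coefficient.

    Neighborhood connectivity is the mean degree of a node's neighbors
    (0 for isolated nodes); the clustering coefficient is the fraction
    of possible edges among neighbors that exist (0 for degree <= 1).
    """
    g = net.graph
    deg = dict(g.degree())
    cc = nx.clustering(g)
    rows = []
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        conn = float(np.mean([deg[m] for m in nbrs])) if nbrs else 0.0
        rows.append(
            {
                "node": node,
                "kind": g.nodes[node].get("kind", ""),
                "degree": deg[node],
                "neighborhood_connectivity": conn,
                "clustering_coefficient": float(cc[node]),
            }
        )
    return pd.DataFrame(rows)


def edge_table(net: CorrelationNetwork) -> pd.DataFrame:
    rows = [
        {
            "source": u,
            "target": v,
            "r": d["r"],
            "r2": d["r2"],
            "weight": d["weight"],
        }
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "r2", "weight"])


def write_graphml(net: CorrelationNetwork, path: str | Path) -> None:
    """Export with node kind + topology metrics and edge r/r2/weight."""
    g = net.graph.copy()
    metrics = node_metrics(net).set_index("node")
    for node in g.nodes:
        g.nodes[node]["degree"] = int(metrics.loc[node, "degree"])
        g.nodes[node]["neighborhood_connectivity"] = float(
            metrics.loc[node, "neighborhood_connectivity"]
        )
        g.nodes[node]["clustering_coefficient"] = float(
            metrics.loc[node, "clustering_coefficient"]
        )
    nx.write_graphml(g, str(path))
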