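"""Genetic network representation, spanning trees, betweenness, ranking.

The genetic network's nodes are (clustered) breeding sites with projected
coordinates; edges carry a non-negative genetic-covariance weight and,
optionally, a betweenness attribute computed upstream. Corridor
prioritization ranks the edges of the network's spanning tree by
betweenness: the tree edges are the backbone along which range-wide gene
flow must pass, and betweenness scores how many node pairs each one
serves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["GeneticNetwork", "EdgeRanking", "spanning_tree",
           "edge_betweenness", "rank_mst_edges"]

logger = logging.getLogger(__name__)

_WEIGHT_FLOOR = 1e-12


class InvalidWeightError(ValueError):
    """An edge weight is unusable under the requested length rule."""


@dataclass
class GeneticNetwork:
    """Weighted genetic network.

    nodes : DataFrame with columns id, x, y (ids unique)
    edges : DataFrame with columns id, node_a, node_b, weight and optional
            betweenness / in_mst
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.nodes = self.nodes.reset_index(drop=True)
        self.edges = self.edges.reset_index(drop=True)
        if self.nodes["id"].duplicated().any():
            raise ValueError("node ids must be unique")
        if (self.edges["node_a"] == self.edges["node_b"]).any():
            raise ValueError("self-loop edges are not allowed")
        key = self.edges.apply(
            lambda e: frozenset((e["node_a"], e["node_b"])), axis=1)
        if key.duplicated().any():
            raise ValueError("at most one edge per unordered node pair")
        w = self.edges["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("edge weights must be finite and non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes["id"])
        # ascending edge id so that stable tie-breaks follow id order
        for e in self.edges.sort_values("id").itertuples(index=False):
            g.add_edge(e.node_a, e.node_b, weight=float(e.weight), edge_id=e.id)
        return g

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.to_networkx())


def spanning_tree(network: GeneticNetwork,
                  sense: str = "maximum") -> list:
    """Edge ids of the network's spanning tree over covariance weights.

    The default sense is *maximum* — the tree retaining the greatest summed
    genetic covariance (the usual sense when weights are similarities; the
    minimum tree over distance-like weights is available via
    ``sense="minimum"``). Ties in weight break on ascending edge id.
    On a disconnected network a per-component forest is returned with a
    logged warning. The ``in_mst`` flag is written back onto the edge
    table.
    """
    if sense not in ("maximum", "minimum"):
        raise ValueError("sense must be 'maximum' or 'minimum'")
    g = network.to_networkx()
    if network.n_nodes and not nx.is_connected(g):
        comps = [sorted(c, key=str) for c in nx.connected_components(g)]
        logger.warning("network is disconnected (%d components: %s); "
                       "returning a spanning forest", len(comps), comps)
    # Kruskal with stable sort: ties resolve in insertion (= edge id) order
    algo = nx.maximum_spanning_edges if sense == "maximum" else nx.minimum_spanning_edges
    tree_ids = sorted(d["edge_id"] for _, _, d in
                      algo(g, algorithm="kruskal", data=True))
    network.edges["in_mst"] = network.edges["id"].isin(tree_ids)
    return tree_ids


def edge_betweenness(network: GeneticNetwork,
                     length_rule: str = "reciprocal-weight") -> pd.Series:
    """Shortest-path edge betweenness, indexed by edge id.

    With ``length_rule="reciprocal-weight"`` an edge's path length is
    1/weight, so high-covariance edges attract shortest paths;
    ``"unit"`` treats every edge as length 1. Counts are raw (one unit per
    unordered node pair) with equal-length multiplicities split
    fractionally.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    g = network.to_networkx()
    if length_rule == "reciprocal-weight":
        w = nx.get_edge_attributes(g, "weight")
        if any(v <= 0 for v in w.values()):
            raise InvalidWeightError(
                "zero/negative weight invalid under reciprocal-weight lengths")
        nx.set_edge_attributes(g, {e: 1.0 / v for e, v in w.items()}, "length")
        bc = nx.edge_betweenness_centrality(g, weight="length", normalized=False)
    elif length_rule == "unit":
        bc = nx.edge_betweenness_centrality(g, weight=None, normalized=False)
    else:
        raise ValueError(f"unknown length_rule {length_rule!r}")
    out = {g.edges[e]["edge_id"]: v for e, v in bc.items()}
    return pd.Series(out, name="betweenness").sort_index()


@dataclass
class EdgeRanking:
    """Ranked spanning-tree edges (rank 1 = highest betweenness)."""

    table: pd.DataFrame  # rank, edge_id, node_a, node_b, betweenness, source
    source: str = field(default="computed")  # {"provided", "computed"}

    def __post_init__(self) -> None:
        b = self.table["betweenness"].to_numpy(dtype=float)
        if np.any(np.diff(b) > 0):
            raise ValueError("betweenness must be non-increasing with rank")

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)


def rank_mst_edges(network: GeneticNetwork, use_provided: bool = True,
                   top_k: Optional[int] = None,
                   length_rule: str = "reciprocal-weight") -> EdgeRanking:
    """Rank the spanning-tree edges by betweenness, descending.

    A ``betweenness`` column already present on the edge table is preferred
    when ``use_provided`` (it may encode a different upstream convention);
    otherwise betweenness is computed here. Ties break on ascending edge
    id. ``top_k`` beyond the tree size returns the whole tree.
    """
    if "in_mst" not in network.edges.columns:
        spanning_tree(network)
    mst = network.edges[network.edges["in_mst"].astype(bool)].copy()

    provided = ("betweenness" in mst.columns
                and mst["betweenness"].notna().all())
    if use_provided and not provided and "betweenness" not in network.edges.columns:
        logger.warning("no provided betweenness attribute; computing it")
    elif use_provided and not provided:
        logger.warning("provided betweenness incomplete on MST edges; computing it")
    if use_provided and provided:
        source = "provided"
    else:
        bc = edge_betweenness(network, length_rule=length_rule)
        mst["betweenness"] = mst["id"].map(bc)
        source = "computed"

    mst = mst.sort_values(["betweenness", "id"],
                          ascending=[False, True], kind="mergesort")
    if top_k is not None:
        mst = mst.head(top_k)
    table = pd.DataFrame({
        "rank": np.arange(1, len(mst) + 1),
        "edge_id": mst["id"].to_numpy(),
        "node_a": mst["node_a"].to_numpy(),
        "node_b": mst["node_b"].to_numpy(),
        "betweenness": mst["betweenness"].to_numpy(dtype=float),
        "source": source,
    })
    return EdgeRanking(table, source=source)
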