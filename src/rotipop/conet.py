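"""Spearman co-occurrence networks and keystone-taxon selection.

Edges connect taxa whose abundance profiles across samples correlate
strongly (|rho| above a threshold, default 0.5) and significantly
(p below 0.05, t-approximation with n-2 df); the correlation sign is kept
as an edge attribute.  Node centralities are the normalized degree
(degree / (n-1)), closeness with reachable-set scaling for disconnected
graphs, pair-normalized betweenness and the local clustering coefficient.

Keystone taxa are nodes jointly extreme in all three centralities: degree
and closeness at or above their top-k order statistic and betweenness at
or below the k-th smallest — the "combined top-k threshold" rule used for
microbial co-occurrence networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import kruskal_wallis
from .otu_pipeline import OtuTable, aggregate_taxonomy, top_k_taxa

__all__ = [
    "spearman_matrix",
    "build_network",
    "node_metrics",
    "graph_metrics",
    "keystone",
    "KeystoneReport",
    "stage_composition_tests",
]


def spearman_matrix(abundances: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and p over taxa (rows) x samples (columns).

    Average ranks break ties; p comes from the t-approximation with n-2
    degrees of freedom.  Zero-variance taxa have undefined correlations,
    reported as NaN.
    """
    if abundances.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if abundances.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    arr = abundances.to_numpy(dtype=float)
    constant = arr.std(axis=1) == 0
    n_taxa = arr.shape[0]
    rho = np.full((n_taxa, n_taxa), np.nan)
    p = np.full((n_taxa, n_taxa), np.nan)
    ok = np.where(~constant)[0]
    if ok.size >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_ok, p_ok = stats.spearmanr(arr[ok], axis=1)
        if np.ndim(r_ok) == 0:  # scipy returns a scalar for 2 variables
            r_ok = np.array([[1.0, r_ok], [r_ok, 1.0]])
            p_ok = np.array([[0.0, p_ok], [p_ok, 0.0]])
        rho[np.ix_(ok, ok)] = r_ok
        p[np.ix_(ok, ok)] = p_ok
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    idx = abundances.index
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_min: float = 0.5,
    p_max: float = 0.05,
    use_abs: bool = True,
) -> nx.Graph:
    """Threshold the correlation matrices into an undirected graph.

    An edge joins two taxa iff ``|rho| > rho_min`` (or ``rho > rho_min``
    with ``use_abs=False``) and ``p < p_max``; NaN correlations never form
    edges.  All taxa stay as nodes so isolated taxa keep zero centralities.
    """
    if rho.shape != p.shape or list(rho.index) != list(p.index):
        raise ValueError("rho and p matrices are not aligned")
    g = nx.Graph()
    g.add_nodes_from(rho.index)
    labels = list(rho.index)
    r = rho.to_numpy()
    pv = p.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rij, pij = r[i, j], pv[i, j]
            if np.isnan(rij) or np.isnan(pij):
                continue
            strength = abs(rij) if use_abs else rij
            if strength > rho_min and pij < p_max:
                g.add_edge(
                    labels[i],
                    labels[j],
                    rho=float(rij),
                    p=float(pij),
                    sign=1 if rij > 0 else -1,
                )
    return g


def node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Normalized degree, closeness, betweenness and clustering per node."""
    n = net.number_of_nodes()
    if n == 0:
        return pd.DataFrame(columns=["degree", "closeness", "betweenness", "clustering"])
    degree = (
        nx.degree_centrality(net)
        if n > 1
        else {v: 0.0 for v in net.nodes}
    )
    closeness = nx.closeness_centrality(net)  # wf_improved reachable scaling
    if n > 2:
        betweenness = nx.betweenness_centrality(net, normalized=True)
    else:
        betweenness = {v: 0.0 for v in net.nodes}
    clustering = nx.clustering(net)
    frame = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "closeness": pd.Series(closeness),
            "betweenness": pd.Series(betweenness),
            "clustering": pd.Series(clustering),
        }
    )
    return frame.loc[list(net.nodes)]


def graph_metrics(net: nx.Graph) -> dict:
    """Average degree (2E/n), average clustering, and diameter plus average
    shortest path length over the largest connected component."""
    n = net.number_of_nodes()
    if n == 0 or net.number_of_edges() == 0:
        warnings.warn("empty network: graph metrics are zero", stacklevel=2)
        return {
            "n_nodes": n,
            "n_edges": 0,
            "avg_degree": 0.0,
            "avg_clustering": 0.0,
            "diameter": 0,
            "avg_shortest_path": 0.0,
        }
    comps = sorted(nx.connected_components(net), key=len, reverse=True)
    giant = net.subgraph(comps[0])
    if giant.number_of_nodes() > 1:
        diameter = int(nx.diameter(giant))
        aspl = float(nx.average_shortest_path_length(giant))
    else:
        diameter, aspl = 0, 0.0
    return {
        "n_nodes": n,
        "n_edges": net.number_of_edges(),
        "avg_degree": 2.0 * net.number_of_edges() / n,
        "avg_clustering": float(nx.average_clustering(net)),
        "diameter": diameter,
        "avg_shortest_path": aspl,
    }


@dataclass(frozen=True)
class KeystoneReport:
    """Combined top-k threshold selection of keystone taxa."""

    degree_min: float
    closeness_min: float
    betweenness_max: float
    selected: list
    table: pd.DataFrame  # per-node metrics with pass/fail flags
    top_k: int

    def reapply(self) -> list:
        """Re-derive the selected set from the stored thresholds (identity)."""
        t = self.table
        mask = (
            (t["degree"] >= self.degree_min)
            & (t["closeness"] >= self.closeness_min)
            & (t["betweenness"] <= self.betweenness_max)
            & t["connected"]
        )
        return sorted(t.index[mask])


def keystone(net: nx.Graph, top_k: int = 20) -> KeystoneReport:
    """Keystone taxa by the combined top-k rule on three centralities.

    Thresholds are the top_k-th order statistics: highest degrees (>=),
    highest closeness (>=) and lowest betweenness (<=).  A node is keystone
    iff it passes all three.  ``top_k`` larger than the node count is
    clipped with a warning.
    """
    metrics = node_metrics(net)
    n = len(metrics)
    if n == 0:
        raise ValueError("network has no nodes")
    if top_k > n:
        warnings.warn(f"top_k={top_k} clipped to n={n}", stacklevel=2)
        top_k = n
    deg_sorted = np.sort(metrics["degree"].to_numpy())[::-1]
    clo_sorted = np.sort(metrics["closeness"].to_numpy())[::-1]
    bet_sorted = np.sort(metrics["betweenness"].to_numpy())
    degree_min = float(deg_sorted[top_k - 1])
    closeness_min = float(clo_sorted[top_k - 1])
    betweenness_max = float(bet_sorted[top_k - 1])
    table = metrics.copy()
    table["pass_degree"] = table["degree"] >= degree_min
    table["pass_closeness"] = table["closeness"] >= closeness_min
    table["pass_betweenness"] = table["betweenness"] <= betweenness_max
    # isolated nodes are never keystones even if thresholds degenerate to 0;
    # connectivity is part of the rule so the report round-trips exactly
    table["connected"] = pd.Series(
        {v: net.degree(v) > 0 for v in net.nodes}
    ).loc[table.index]
    mask = (
        table["pass_degree"]
        & table["pass_closeness"]
        & table["pass_betweenness"]
        & table["connected"]
    )
    selected = sorted(table.index[mask])
    return KeystoneReport(
        degree_min=degree_min,
        closeness_min=closeness_min,
        betweenness_max=betweenness_max,
        selected=selected,
        table=table,
        top_k=top_k,
    )


def stage_composition_tests(
    table: OtuTable,
    by: str = "stage",
    rank: str = "genus",
    top_n: int = 15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis tests of relative abundance across stages.

    Aggregates to ``rank``, keeps the ``top_n`` taxa by mean relative
    abundance and tests each across the levels of ``by`` (>= 2 levels with
    >= 2 samples each).  Returns H, p and a significance flag at ``alpha``.
    """
    levels = table.metadata[by].unique().tolist()
    if len(levels) < 2:
        raise ValueError(f"need >= 2 levels of {by!r}")
    for lvl in levels:
        if (table.metadata[by] == lvl).sum() < 2:
            raise ValueError(f"level {lvl!r} has fewer than 2 samples")
    agg = aggregate_taxonomy(table, rank)
    top = top_k_taxa(agg, k=top_n)
    totals = agg.sum(axis=1)
    rel = agg.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    rows = []
    for taxon in top:
        groups = [
            rel.loc[table.metadata.index[table.metadata[by] == lvl], taxon].to_numpy()
            for lvl in levels
        ]
        res = kruskal_wallis(groups, exact="never")
        rows.append(
            {
                "taxon": taxon,
                "mean_rel_abundance": float(rel[taxon].mean()),
                "H": res["H"],
                "p": res["p"],
                "significant": res["p"] < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")
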