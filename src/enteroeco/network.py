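"""Thresholded correlation co-occurrence networks and their topology.

Taxa passing a total-relative-abundance filter are correlated pairwise
across samples (Spearman by default; Pearson selectable); edges keep
pairs whose |r| clears the configured cutoff at the configured p. Node
and edge counts, degree, clustering and greedy modularity are the metrics
compared between enterotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable, ConfigError

__all__ = [
    "Network",
    "build_network",
    "network_metrics",
    "detect_modules",
    "edge_table",
    "write_graphml",
]


@dataclass
class Network:
    graph: nx.Graph
    r_threshold: float
    p_threshold: float
    corr_method: str
    n_filtered_taxa: int                  # taxa passing the abundance filter
    isolated_taxa: list[str] = field(default_factory=list)


def _pearson_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r matrix with two-sided p-values from the t distribution."""
    n = X.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr ** 2))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    np.fill_diagonal(p, 0.0)
    return r, p


def _spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    return _pearson_matrix(ranks)


def build_network(table: AbundanceTable, min_total_rel_abund: float = 0.005,
                  corr_method: str = "spearman", r_threshold: float = 0.7,
                  p_threshold: float = 0.05, bh_correct: bool = False,
                  include_isolated: bool = False) -> Network:
    """Build a co-occurrence network for one group of samples.

    Taxa whose share of the table's grand total exceeds
    ``min_total_rel_abund`` (default 0.5%) are retained; edges connect
    pairs with |r| > ``r_threshold`` and p < ``p_threshold``. Isolated
    filtered taxa are excluded from the node set unless
    ``include_isolated``. ``bh_correct`` applies Benjamini-Hochberg to the
    edge p-values (off by default).
    """
    if table.n_samples < 5:
        raise ConfigError("build_network needs at least 5 samples")
    if not (0 < r_threshold < 1) or not (0 < p_threshold < 1):
        raise ConfigError("thresholds must lie in (0, 1)")
    if corr_method not in ("spearman", "pearson"):
        raise ConfigError(f"unknown corr_method {corr_method!r}")
    share = table.data.sum(axis=0) / table.values.sum()
    kept = share.index[share > min_total_rel_abund].tolist()
    g = nx.Graph()
    if len(kept) < 2:
        warnings.warn("fewer than 2 taxa survive the abundance filter; "
                      "empty network", stacklevel=2)
        return Network(graph=g, r_threshold=r_threshold, p_threshold=p_threshold,
                       corr_method=corr_method, n_filtered_taxa=len(kept),
                       isolated_taxa=list(kept) if include_isolated else [])
    X = table.data[kept].to_numpy(dtype=float)
    corr_fn = _spearman_matrix if corr_method == "spearman" else _pearson_matrix
    r, p = corr_fn(X)
    iu = np.triu_indices(len(kept), k=1)
    r_flat, p_flat = r[iu], p[iu]
    if bh_correct:
        p_flat = multipletests(p_flat, method="fdr_bh")[1]
    keep_edge = (np.abs(r_flat) > r_threshold) & (p_flat < p_threshold)
    for (i, j, rv, pv) in zip(iu[0][keep_edge], iu[1][keep_edge],
                              r_flat[keep_edge], p_flat[keep_edge]):
        g.add_edge(kept[i], kept[j], r=float(rv), p=float(pv),
                   sign="positive" if rv > 0 else "negative")
    isolated = sorted(set(kept) - set(g.nodes))
    if include_isolated:
        g.add_nodes_from(isolated)
    # annotate nodes with their table-wide relative abundance (and phylum
    # when a taxonomy map is attached)
    for node in g.nodes:
        g.nodes[node]["total_rel_abund"] = float(share[node])
        if table.taxonomy and node in table.taxonomy:
            tokens = str(table.taxonomy[node]).split(";")
            if len(tokens) > 1:
                g.nodes[node]["phylum"] = tokens[1].strip()
    return Network(graph=g, r_threshold=r_threshold, p_threshold=p_threshold,
                   corr_method=corr_method, n_filtered_taxa=len(kept),
                   isolated_taxa=isolated)


def network_metrics(net: Network) -> dict:
    """Node/edge counts, average degree 2E/V, mean local clustering
    (degree<2 nodes contribute 0) and edge-sign shares."""
    g = net.graph
    n_nodes, n_edges = g.number_of_nodes(), g.number_of_edges()
    if n_nodes == 0:
        return {"n_nodes": 0, "n_edges": 0, "average_degree": 0.0,
                "average_clustering": 0.0, "positive_proportion": 0.0,
                "negative_proportion": 0.0, "empty": True}
    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    pos = signs.count("positive")
    neg = signs.count("negative")
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "average_degree": 2.0 * n_edges / n_nodes,
        "average_clustering": float(nx.average_clustering(g)) if n_edges else 0.0,
        "positive_proportion": pos / n_edges if n_edges else 0.0,
        "negative_proportion": neg / n_edges if n_edges else 0.0,
        "empty": n_edges == 0,
    }


def detect_modules(net: Network, seed: int = 0) -> tuple[dict, float]:
    """Greedy (CNM) modularity maximisation on the unweighted edge set.

    Returns (node -> module index, modularity Q of that partition).
    Deterministic: communities are ordered by (size, smallest node id).
    ``seed`` is accepted for interface stability; the greedy algorithm is
    deterministic and does not consume it.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        raise ConfigError("module detection needs at least one edge")
    comms = nx.community.greedy_modularity_communities(g, weight=None)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    membership = {node: i for i, c in enumerate(comms) for node in c}
    q = nx.community.modularity(g, [set(c) for c in comms], weight=None)
    return membership, float(q)


def write_graphml(net: Network, path) -> None:
    """Write the network as GraphML for external visualisation tools."""
    nx.write_graphml(net.graph, str(path))


def edge_table(net: Network) -> pd.DataFrame:
    """Edge list as a tidy frame (taxon_i, taxon_j, r, p, sign)."""
    rows = [
        {"taxon_i": u, "taxon_j": v, "r": d["r"], "p": d["p"], "sign": d["sign"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "r", "p", "sign"])
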