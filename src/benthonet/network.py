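"""Species co-occurrence networks from pairwise Spearman correlations.

Taxa are nodes; an edge joins two taxa whose abundances are significantly
rank-correlated across samples. Six summary statistics describe community
structure complexity: node count, edge count, average node degree, average
shortest-path length, transitivity (global clustering coefficient) and edge
density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityMatrix

__all__ = [
    "CorrelationMatrix",
    "CooccurrenceNetwork",
    "NetworkSummary",
    "spearman_matrix",
    "build_network",
    "network_summary",
    "edge_list",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman rho and two-sided p-values among taxa.

    Zero-variance taxa have undefined (NaN) correlations and never enter the
    graph.
    """

    taxon_ids: tuple[str, ...]
    rho: np.ndarray
    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        k = len(self.taxon_ids)
        if self.rho.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("rho/p shape must match taxon count")


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Undirected species graph plus a record of the edge rule that built it."""

    graph: nx.Graph
    edge_rule: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return list(self.graph.edges)


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_path_length: float
    transitivity: float
    edge_density: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "avg_path_length": self.avg_path_length,
            "transitivity": self.transitivity,
            "edge_density": self.edge_density,
        }


def spearman_matrix(m: CommunityMatrix) -> CorrelationMatrix:
    """All-pairs Spearman rank correlation with the t approximation.

    rho is the Pearson correlation of mid-ranks (average ranks for ties);
    the two-sided p-value uses t = rho·√((n−2)/(1−rho²)) on n − 2 degrees of
    freedom. Requires at least 3 samples.
    """
    X = m.counts
    n, k = X.shape
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    ranks = stats.rankdata(X, axis=0)  # mid-ranks
    sd = ranks.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |rho| == 1
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    if degenerate.any():
        names = [m.taxon_ids[i] for i in np.nonzero(degenerate)[0]]
        warnings.warn(
            f"{degenerate.sum()} zero-variance taxa excluded from correlations: "
            f"{names[:5]}...",
            stacklevel=2,
        )
    return CorrelationMatrix(
        taxon_ids=tuple(m.taxon_ids), rho=rho, p=p, n_samples=n
    )


def build_network(
    c: CorrelationMatrix,
    alpha: float = 0.05,
    min_abs_rho: float = 0.0,
    signed: str = "both",
) -> CooccurrenceNetwork:
    """Threshold the correlation matrix into an undirected species graph.

    Edge (i, j) exists iff p < ``alpha`` and |rho| ≥ ``min_abs_rho`` (and
    rho > 0 under ``signed='positive_only'``). All taxa remain as nodes, so
    isolated species still count toward network size.
    """
    if signed not in ("both", "positive_only"):
        raise ValueError(f"unknown signed mode {signed!r}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(c.taxon_ids)
    k = len(c.taxon_ids)
    for i in range(k):
        for j in range(i + 1, k):
            rho, p = c.rho[i, j], c.p[i, j]
            if np.isnan(rho):
                continue
            if p < alpha and abs(rho) >= min_abs_rho and (
                signed == "both" or rho > 0
            ):
                g.add_edge(c.taxon_ids[i], c.taxon_ids[j], rho=float(rho), p=float(p))
    rule = {"alpha": alpha, "min_abs_rho": min_abs_rho, "signed": signed}
    return CooccurrenceNetwork(graph=g, edge_rule=rule)


def network_summary(net: CooccurrenceNetwork | nx.Graph) -> NetworkSummary:
    """The six graph statistics summarizing community structure complexity.

    Average path length is the mean shortest-path length over connected
    ordered pairs; pairs in different components are excluded. With no
    connected pair (or a single node) it is NaN. Transitivity is
    3 × triangles / connected triples.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    e = g.number_of_edges()
    avg_degree = 2.0 * e / n
    density = e / (n * (n - 1) / 2.0) if n > 1 else float("nan")

    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    pairs += 1
    apl = total / pairs if pairs else float("nan")

    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        avg_degree=avg_degree,
        avg_path_length=apl,
        transitivity=float(nx.transitivity(g)),
        edge_density=density,
    )


def edge_list(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Edge table (taxon_i, taxon_j, rho, p) for TSV export."""
    rows = [
        (u, v, d.get("rho", np.nan), d.get("p", np.nan))
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "rho", "p"])


def grouped_summaries(
    m: CommunityMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    min_abs_rho: float = 0.0,
    signed: str = "both",
) -> pd.DataFrame:
    """Per-group network summary table (one row per group, e.g. per stream).

    Taxa absent from every sample of a group are dropped before correlation,
    so node counts equal per-group species totals.
    """
    rows = {}
    for gname in groups.drop_duplicates():
        sub = m.data.loc[groups[groups == gname].index]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        cm = CommunityMatrix(sub, transformed=m.transformed, log_base=m.log_base)
        net = build_network(
            spearman_matrix(cm), alpha=alpha, min_abs_rho=min_abs_rho, signed=signed
        )
        rows[gname] = network_summary(net).as_dict()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
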