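"""Spearman co-expression network construction and topology metrics.

All retained gene pairs are correlated with Spearman's rho (mid-rank tie
handling; two-sided p from the large-sample t approximation), the upper
triangle of p-values is BH-adjusted, and an edge is kept iff
``|rho| > r_threshold`` AND ``q <= q_threshold``. Isolated genes are not
network members, matching reported node counts that fall below the filtered
gene count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "CorrelationResult",
    "NetworkMetrics",
    "bh_adjust",
    "spearman_all_pairs",
    "build_network",
    "topology_metrics",
    "edges_to_frame",
    "network_from_edges",
]


@dataclass
class CorrelationResult:
    """Symmetric rho / p / BH-q matrices over a common gene index."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    density: float
    avg_clustering: float
    n_components: int
    largest_component_fraction: float

    def to_jsonable(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "avg_clustering": self.avg_clustering,
            "n_components": self.n_components,
            "largest_component_fraction": self.largest_component_fraction,
        }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1).

    Standard step-up: sort ascending, multiply p(i) by m/i, then take the
    cumulative minimum from the largest rank down; original order restored.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise DataError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def spearman_all_pairs(expr: pd.DataFrame) -> CorrelationResult:
    """All-pairs Spearman correlation with BH FDR over the upper triangle.

    Constant genes (zero rank variance) get rho 0 / p 1 against every other
    gene rather than an error; the diagonal is rho 1 with p = q = 0 and is
    excluded from the BH family.
    """
    n_genes, n_samples = expr.shape
    if n_samples < 3:
        raise DataError("need at least 3 samples for correlation testing")
    if n_genes < 2:
        raise DataError("need at least 2 genes")
    values = expr.to_numpy()
    res = stats.spearmanr(values.T)
    rho = np.array(res.statistic, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    if rho.ndim == 0:  # scipy collapses the 2-gene case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    constant = values.std(axis=1) == 0
    if constant.any():
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
        p[constant, :] = 1.0
        p[:, constant] = 1.0
    # any residual NaN (e.g. all-tie pathologies) is treated as no evidence
    rho = np.nan_to_num(rho, nan=0.0)
    p[np.isnan(p)] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(n_genes, k=1)
    q = np.zeros_like(p)
    q_flat = bh_adjust(p[iu])
    q[iu] = q_flat
    q = q + q.T
    idx = expr.index
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        q=pd.DataFrame(q, index=idx, columns=idx),
    )


def build_network(
    corr: CorrelationResult,
    r_threshold: float = 0.8,
    q_threshold: float = 0.05,
    organ: str | None = None,
) -> nx.Graph:
    """Threshold the correlation result into an undirected weighted graph.

    Edge kept iff ``|rho| > r_threshold`` and ``q <= q_threshold``; weight is
    ``|rho|`` and the signed correlation is stored as ``signed_rho``.
    Isolated genes are dropped from the node set.
    """
    if not (0.0 < r_threshold < 1.0) or not (0.0 < q_threshold < 1.0):
        raise DataError("thresholds must lie in (0, 1)")
    rho = corr.rho.to_numpy()
    q = corr.q.to_numpy()
    genes = list(corr.rho.index)
    iu = np.triu_indices(len(genes), k=1)
    keep = (np.abs(rho[iu]) > r_threshold) & (q[iu] <= q_threshold)
    g = nx.Graph(organ=organ)
    rows, cols = iu[0][keep], iu[1][keep]
    for i, j in zip(rows, cols):
        g.add_edge(
            genes[i],
            genes[j],
            weight=float(abs(rho[i, j])),
            signed_rho=float(rho[i, j]),
            q=float(q[i, j]),
        )
    if g.number_of_edges() == 0:
        warnings.warn("no edges survive the thresholds; network is empty")
    return g


def topology_metrics(net: nx.Graph) -> NetworkMetrics:
    """Density, average local clustering, and component structure."""
    v = net.number_of_nodes()
    e = net.number_of_edges()
    if v == 0:
        return NetworkMetrics(0, 0, 0.0, 0.0, 0, 0.0)
    density = 2.0 * e / (v * (v - 1)) if v >= 2 else 0.0
    avg_clustering = nx.average_clustering(net)  # degree<2 nodes contribute 0
    components = list(nx.connected_components(net))
    largest = max(len(c) for c in components)
    return NetworkMetrics(
        n_nodes=v,
        n_edges=e,
        density=density,
        avg_clustering=avg_clustering,
        n_components=len(components),
        largest_component_fraction=largest / v,
    )


def edges_to_frame(net: nx.Graph) -> pd.DataFrame:
    """Edge list as a (gene_a, gene_b, rho, q) DataFrame, sorted for stability."""
    rows = [
        (min(a, b), max(a, b), d["signed_rho"], d["q"])
        for a, b, d in net.edges(data=True)
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "q"])


def network_from_edges(edges: pd.DataFrame, organ: str | None = None) -> nx.Graph:
    """Rebuild a co-expression graph from an edge-list frame."""
    g = nx.Graph(organ=organ)
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.gene_a,
            row.gene_b,
            weight=abs(float(row.rho)),
            signed_rho=float(row.rho),
            q=float(row.q),
        )
    return g
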