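"""Pearson co-expression network over candidate genes and hub calling.

Pairwise Pearson correlations are computed across samples on
log2(FPKM + 1); gene pairs whose correlation strictly exceeds the
threshold (default 0.6; signed mode r > t, absolute mode |r| > t) become
edges of an undirected network, and hub genes are the nodes of highest
connectivity (degree), ties broken by summed absolute edge weight then
gene name.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["pearson", "build_network", "hub_genes", "edge_table", "node_table"]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN when either vector has zero
    variance (no defined correlation). Requires equal lengths >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return float("nan")
    return float((xd * yd).sum() / denom)


def build_network(
    expr: pd.DataFrame,
    genes: Iterable[str] | None = None,
    threshold: float = 0.6,
    mode: Literal["signed", "absolute"] = "signed",
    log_transform: bool = True,
) -> nx.Graph:
    """Co-expression graph over candidate genes.

    ``expr`` is genes x samples (FPKM scale unless ``log_transform`` is
    disabled, in which case values are used as given). An edge joins two
    genes iff r > threshold (signed) or |r| > threshold (absolute), strict
    either way; a constant gene yields undefined correlations and no edges.
    Fewer than two candidates gives an empty network.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = expr if genes is None else expr.loc[[g for g in genes if g in expr.index]]
    graph = nx.Graph()
    graph.add_nodes_from(sub.index)
    if len(sub) < 2:
        return graph
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    values = np.log2(sub.to_numpy(float) + 1.0) if log_transform else sub.to_numpy(float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    names = list(sub.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if np.isnan(r):
                continue
            stat = abs(r) if mode == "absolute" else r
            if stat > threshold:
                graph.add_edge(names[i], names[j], r=float(r))
    return graph


def hub_genes(net: nx.Graph, k: int = 2) -> list[str]:
    """Top-k genes by connectivity (degree), ties broken by summed |r| then
    lexicographic name. k beyond the node count returns all nodes with a
    warning; an empty network is an error."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no hubs")
    if k > net.number_of_nodes():
        warnings.warn(
            f"requested {k} hubs from a {net.number_of_nodes()}-node network; returning all",
            stacklevel=2,
        )
        k = net.number_of_nodes()

    def strength(node) -> float:
        return sum(abs(d["r"]) for _, _, d in net.edges(node, data=True))

    ranked = sorted(net.nodes, key=lambda n: (-net.degree(n), -strength(n), n))
    return ranked[:k]


def edge_table(net: nx.Graph) -> pd.DataFrame:
    rows = [{"gene_a": a, "gene_b": b, "r": d["r"]} for a, b, d in net.edges(data=True)]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])


def node_table(net: nx.Graph) -> pd.DataFrame:
    rows = [{"gene": n, "degree": net.degree(n)} for n in sorted(net.nodes)]
    return pd.DataFrame(rows, columns=["gene", "degree"])
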