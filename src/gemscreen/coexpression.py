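"""Gene co-expression networks and random-walk communities.

The network has an edge for every gene pair whose Pearson correlation
reaches a cutoff (default 0.99, applied to the signed value; a quantile mode
keeping the top fraction of pairs is available as an alternative reading of
"top 1% correlated pairs").  Communities come from the Walktrap algorithm —
agglomerative merging on short-random-walk distances, cut at maximum
modularity — and are then filtered on size and mean intra-cluster
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import igraph as ig
import numpy as np
import pandas as pd

__all__ = [
    "correlation_matrix",
    "CoexpressionNetwork",
    "build_network",
    "walktrap_communities",
    "GeneCluster",
    "filter_clusters",
    "top_neighbors",
]


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between all gene pairs (genes are rows).

    Constant genes have undefined correlations; their entries are NaN and are
    excluded downstream.  Requires at least 3 samples.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    X = expr.to_numpy(float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.asarray(R, float)
    constant = sd == 0
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    np.fill_diagonal(R, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(R, index=expr.index, columns=expr.index)


@dataclass
class CoexpressionNetwork:
    """Simple weighted graph over genes; every edge weight >= the cutoff used."""

    nodes: List[str]
    edges: List[Tuple[str, str, float]]
    cutoff: float

    @property
    def graph(self) -> ig.Graph:
        g = ig.Graph()
        g.add_vertices(self.nodes)
        g.add_edges([(a, b) for a, b, _ in self.edges])
        g.es["weight"] = [w for _, _, w in self.edges]
        return g

    def write_sif(self, path: Union[str, Path]) -> None:
        lines = [f"{a}\tco\t{b}" for a, b, _ in self.edges]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_graphml(self, path: Union[str, Path]) -> None:
        self.graph.write_graphml(str(path))


def build_network(
    corr: pd.DataFrame,
    cutoff: float = 0.99,
    mode: str = "threshold",
) -> CoexpressionNetwork:
    """Build the co-expression network from a correlation matrix.

    ``threshold`` mode keeps pairs with r >= cutoff; ``quantile`` mode treats
    ``cutoff`` as the fraction of top-correlated pairs to keep (e.g. 0.01).
    Isolated genes are excluded from the node set.
    """
    genes = list(corr.index)
    R = corr.to_numpy(float)
    iu = np.triu_indices(len(genes), k=1)
    vals = R[iu]
    valid = ~np.isnan(vals)
    if mode == "threshold":
        keep = valid & (vals >= cutoff)
    elif mode == "quantile":
        n_keep = int(np.floor(cutoff * valid.sum()))
        keep = np.zeros_like(valid)
        if n_keep > 0:
            order = np.argsort(np.where(valid, vals, -np.inf))[::-1][:n_keep]
            keep[order] = True
            keep &= valid
    else:
        raise ValueError(f"unknown network mode {mode!r}")
    edges = [
        (genes[i], genes[j], float(v))
        for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep])
    ]
    nodes = sorted({a for a, _, _ in edges} | {b for _, b, _ in edges})
    return CoexpressionNetwork(nodes, edges, cutoff)


def walktrap_communities(
    network: CoexpressionNetwork, walk_length: int = 4
) -> Dict[str, int]:
    """Partition network genes by the Walktrap random-walk community algorithm.

    Agglomerative merging on walk_length-step random-walk distances, with the
    partition taken at maximum modularity.  Deterministic for a given network.
    Returns gene -> community label (0-based).
    """
    if not network.nodes:
        raise ValueError("empty network")
    g = network.graph
    dendro = g.community_walktrap(weights="weight", steps=walk_length)
    clustering = dendro.as_clustering()
    return {
        g.vs[v]["name"]: int(label)
        for label, comm in enumerate(clustering)
        for v in comm
    }


@dataclass
class GeneCluster:
    cluster_id: int
    members: List[str]
    mean_correlation: float


def filter_clusters(
    partition: Dict[str, int],
    corr: pd.DataFrame,
    min_size: int = 5,
    min_corr: float = 0.5,
) -> List[GeneCluster]:
    """Keep clusters with >= min_size genes and mean pairwise r > min_corr.

    The mean is computed on the full correlation matrix, not on network edge
    weights (edge weights already exceed the network cutoff).
    """
    by_label: Dict[int, List[str]] = {}
    for gene, label in partition.items():
        by_label.setdefault(label, []).append(gene)
    kept = []
    for label in sorted(by_label):
        members = sorted(by_label[label])
        if len(members) < min_size:
            continue
        sub = corr.loc[members, members].to_numpy(float)
        iu = np.triu_indices(len(members), k=1)
        mean_r = float(np.nanmean(sub[iu]))
        if mean_r > min_corr:
            kept.append(GeneCluster(label, members, mean_r))
    return kept


def top_neighbors(
    corr: pd.DataFrame,
    gene: str,
    n: int = 8,
    min_corr: float = 0.9,
) -> List[Tuple[str, float]]:
    """Up to ``n`` genes most correlated with ``gene`` above ``min_corr``.

    Sorted by correlation descending (ties by gene id); self excluded.
    """
    if gene not in corr.index:
        raise KeyError(f"gene {gene!r} not in correlation matrix")
    row = corr.loc[gene].drop(index=gene)
    row = row[row > min_corr].dropna()
    ranked = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, float(r)) for g, r in ranked[:n]]
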